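# Irregular-form exception lexicon for the baseline lemmatizer: surface<TAB>lemma.
children	child
women	woman
men	man
feet	foot
teeth	tooth
mice	mouse
sera	serum
analyses	analysis
matrices	matrix
indices	index
criteria	criterion
phenomena	phenomenon
bacteria	bacterium
fungi	fungus
nuclei	nucleus
foci	focus
larvae	larva
vertebrae	vertebra
people	person
fetuses	fetus
was	be
were	be
is	be
are	be
been	be
being	be
has	have
had	have
did	do
done	do
found	find
ate	eat
eaten	eat
drank	drink
drunk	drink
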