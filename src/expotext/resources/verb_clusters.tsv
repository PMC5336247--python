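# Built-in baseline verb-cluster lexicon: verb lemma -> 3-level semantic class path.
# Columns: verb<TAB>level1<TAB>level2<TAB>level3.  Semantically similar verbs share a
# leaf class (e.g. stimulate/activate), related classes share higher levels.
# A reference lexicon in the same format may be supplied to replace this one.
stimulate	1	1.1	1.1.1
activate	1	1.1	1.1.1
induce	1	1.1	1.1.1
enhance	1	1.1	1.1.1
promote	1	1.1	1.1.1
increase	1	1.1	1.1.2
elevate	1	1.1	1.1.2
raise	1	1.1	1.1.2
inhibit	1	1.2	1.2.1
suppress	1	1.2	1.2.1
block	1	1.2	1.2.1
halt	1	1.2	1.2.1
decrease	1	1.2	1.2.2
reduce	1	1.2	1.2.2
lower	1	1.2	1.2.2
slow	1	1.2	1.2.2
diminish	1	1.2	1.2.2
affect	1	1.3	1.3.1
alter	1	1.3	1.3.1
modify	1	1.3	1.3.1
influence	1	1.3	1.3.1
modulate	1	1.3	1.3.1
change	1	1.3	1.3.1
impair	1	1.3	1.3.2
disrupt	1	1.3	1.3.2
damage	1	1.3	1.3.2
measure	2	2.1	2.1.1
quantify	2	2.1	2.1.1
determine	2	2.1	2.1.1
assay	2	2.1	2.1.1
analyze	2	2.1	2.1.1
detect	2	2.1	2.1.2
identify	2	2.1	2.1.2
observe	2	2.1	2.1.2
find	2	2.1	2.1.2
compare	2	2.2	2.2.1
correlate	2	2.2	2.2.1
associate	2	2.2	2.2.1
estimate	2	2.2	2.2.2
assess	2	2.2	2.2.2
evaluate	2	2.2	2.2.2
predict	2	2.2	2.2.2
model	2	2.2	2.2.2
ingest	3	3.1	3.1.1
consume	3	3.1	3.1.1
eat	3	3.1	3.1.1
drink	3	3.1	3.1.1
inhale	3	3.2	3.2.1
breathe	3	3.2	3.2.1
expose	3	3.3	3.3.1
contaminate	3	3.3	3.3.1
accumulate	3	3.4	3.4.1
absorb	3	3.4	3.4.1
excrete	3	3.4	3.4.2
metabolize	3	3.4	3.4.2
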