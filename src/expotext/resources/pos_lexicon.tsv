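# Closed-class word lexicon for the baseline POS tagger: word<TAB>Penn tag.
the	DT
a	DT
an	DT
this	DT
these	DT
that	DT
those	DT
each	DT
no	DT
of	IN
in	IN
on	IN
at	IN
by	IN
for	IN
from	IN
with	IN
without	IN
among	IN
between	IN
during	IN
after	IN
before	IN
via	IN
per	IN
than	IN
as	IN
into	IN
through	IN
and	CC
or	CC
but	CC
nor	CC
to	TO
is	VBZ
are	VBP
was	VBD
were	VBD
be	VB
been	VBN
being	VBG
has	VBZ
have	VBP
had	VBD
do	VBP
does	VBZ
did	VBD
can	MD
could	MD
may	MD
might	MD
will	MD
would	MD
should	MD
must	MD
not	RB
also	RB
however	RB
we	PRP
it	PRP
they	PRP
he	PRP
she	PRP
i	PRP
our	PRP$
its	PRP$
their	PRP$
his	PRP$
her	PRP$
shows	VBZ
show	VBP
showed	VBD
shown	VBN
reports	VBZ
report	VBP
reported	VBD
describes	VBZ
describe	VBP
described	VBD
presents	VBZ
present	VBP
presented	VBD
suggests	VBZ
suggest	VBP
suggested	VBD
considers	VBZ
consider	VBP
considered	VBD
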