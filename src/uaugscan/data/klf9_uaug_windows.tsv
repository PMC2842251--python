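label	sequence	mutant
uAUG1	cauaAUGgggu	0
uAUG2	aaagAUGuguc	0
uAUG3	gccaAUGccag	0
uAUG4	aaagAUGuguc	0
uAUG5	uuaaAUGucag	0
uAUG6	cgugAUGggau	0
m6	cgugAAGggau	1
uAUG7	gagaAUGccgg	0
m7	gagaAAGccgg	1
uAUG8	gugaAUGuccu	0
uAUG9	guggAUGcugc	0
uAUG10	aaagAUGaggg	0
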