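parent	child
ROOT	IV
ROOT	IX
ROOT	X
ROOT	XI
ROOT	XIII
ROOT	XIV
IV	E10-E14
IV	E65-E68
IV	E70-E90
E10-E14	E10
E10-E14	E11
E65-E68	E65
E65-E68	E66
E70-E90	E78
IX	I10-I15
IX	I20-I25
IX	I30-I52
IX	I60-I69
I10-I15	I10
I10-I15	I15
I20-I25	I20
I20-I25	I21
I20-I25	I25
I30-I52	I30
I30-I52	I50
I60-I69	I60
I60-I69	I63
X	J40-J47
J40-J47	J44
J40-J47	J45
XI	K20-K31
K20-K31	K21
K20-K31	K25
XIII	M05-M14
M05-M14	M05
M05-M14	M10
M05-M14	M11
XIV	N30-N39
N30-N39	N30
N30-N39	N39
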