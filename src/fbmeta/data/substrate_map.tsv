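cazy_family	target
GH18	chitin
GH19	chitin
GH20	chitin
AA11	chitin
CBM14	chitin
GH5	cellulose
GH6	cellulose
GH7	cellulose
GH9	cellulose
GH12	cellulose
GH45	cellulose
AA9	cellulose
CBM1	cellulose
GH16	beta-glucan
GH17	beta-glucan
GH55	beta-glucan
GH64	beta-glucan
GH81	beta-glucan
GH10	hemicellulose branch
GH11	hemicellulose branch
GH43	hemicellulose branch
GH51	hemicellulose branch
GH54	hemicellulose branch
GH62	hemicellulose branch
GH67	hemicellulose branch
GH115	hemicellulose branch
GH26	mannan backbone
GH113	mannan backbone
GH76	mannan
GH38	mannan
GH92	glycoconjugates
GH47	glycoconjugates
GH63	glycoconjugates
GH29	glycoconjugates
GH33	glycoconjugates
GH85	glycoconjugates
GH109	glycoconjugates
GH23	peptidoglycan
GH24	peptidoglycan
GH25	peptidoglycan
GH73	peptidoglycan
GH102	peptidoglycan
GH103	peptidoglycan
GH28	pectin
GH78	pectin
GH88	pectin
PL1	pectin
PL3	pectin
PL9	pectin
CE8	pectin
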