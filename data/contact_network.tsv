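# u	v
m000	f001
f001	m002
m002	f003
f003	m004
m002	f005
f001	m006
m002	f007
f001	m008
m000	f009
f001	m010
m002	f011
f009	m012
m008	f013
f013	m014
m008	f015
f009	m016
m016	f017
f013	m018
m012	f019
f011	m020
m012	f021
f021	m022
m006	f023
f019	m024
m016	f025
f001	m026
m010	f027
f025	m028
m016	f029
f001	m030
m024	f031
f023	m032
m028	f033
f005	m034
m002	f035
f031	m036
m000	f037
f021	m038
m020	f025
m014	f029
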