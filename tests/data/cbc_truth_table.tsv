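pairA	pairB	event
AA	AA	identical
AA	AC	nonCBC
AA	AG	nonCBC
AA	AU	nonCBC
AA	CA	nonCBC
AA	CC	nonCBC
AA	CG	nonCBC
AA	CU	nonCBC
AA	GA	nonCBC
AA	GC	nonCBC
AA	GG	nonCBC
AA	GU	nonCBC
AA	UA	nonCBC
AA	UC	nonCBC
AA	UG	nonCBC
AA	UU	nonCBC
AC	AA	nonCBC
AC	AC	identical
AC	AG	nonCBC
AC	AU	hCBC
AC	CA	combined
AC	CC	nonCBC
AC	CG	combined
AC	CU	nonCBC
AC	GA	nonCBC
AC	GC	hCBC
AC	GG	nonCBC
AC	GU	combined
AC	UA	combined
AC	UC	nonCBC
AC	UG	combined
AC	UU	nonCBC
AG	AA	nonCBC
AG	AC	nonCBC
AG	AG	identical
AG	AU	nonCBC
AG	CA	nonCBC
AG	CC	nonCBC
AG	CG	nonCBC
AG	CU	nonCBC
AG	GA	nonCBC
AG	GC	nonCBC
AG	GG	nonCBC
AG	GU	nonCBC
AG	UA	nonCBC
AG	UC	nonCBC
AG	UG	nonCBC
AG	UU	nonCBC
AU	AA	nonCBC
AU	AC	hCBC
AU	AG	nonCBC
AU	AU	identical
AU	CA	combined
AU	CC	nonCBC
AU	CG	CBC
AU	CU	nonCBC
AU	GA	nonCBC
AU	GC	CBC
AU	GG	nonCBC
AU	GU	hCBC
AU	UA	CBC
AU	UC	nonCBC
AU	UG	combined
AU	UU	nonCBC
CA	AA	nonCBC
CA	AC	combined
CA	AG	nonCBC
CA	AU	combined
CA	CA	identical
CA	CC	nonCBC
CA	CG	hCBC
CA	CU	nonCBC
CA	GA	nonCBC
CA	GC	combined
CA	GG	nonCBC
CA	GU	combined
CA	UA	hCBC
CA	UC	nonCBC
CA	UG	combined
CA	UU	nonCBC
CC	AA	nonCBC
CC	AC	nonCBC
CC	AG	nonCBC
CC	AU	nonCBC
CC	CA	nonCBC
CC	CC	identical
CC	CG	nonCBC
CC	CU	nonCBC
CC	GA	nonCBC
CC	GC	nonCBC
CC	GG	nonCBC
CC	GU	nonCBC
CC	UA	nonCBC
CC	UC	nonCBC
CC	UG	nonCBC
CC	UU	nonCBC
CG	AA	nonCBC
CG	AC	combined
CG	AG	nonCBC
CG	AU	CBC
CG	CA	hCBC
CG	CC	nonCBC
CG	CG	identical
CG	CU	nonCBC
CG	GA	nonCBC
CG	GC	CBC
CG	GG	nonCBC
CG	GU	combined
CG	UA	CBC
CG	UC	nonCBC
CG	UG	hCBC
CG	UU	nonCBC
CU	AA	nonCBC
CU	AC	nonCBC
CU	AG	nonCBC
CU	AU	nonCBC
CU	CA	nonCBC
CU	CC	nonCBC
CU	CG	nonCBC
CU	CU	identical
CU	GA	nonCBC
CU	GC	nonCBC
CU	GG	nonCBC
CU	GU	nonCBC
CU	UA	nonCBC
CU	UC	nonCBC
CU	UG	nonCBC
CU	UU	nonCBC
GA	AA	nonCBC
GA	AC	nonCBC
GA	AG	nonCBC
GA	AU	nonCBC
GA	CA	nonCBC
GA	CC	nonCBC
GA	CG	nonCBC
GA	CU	nonCBC
GA	GA	identical
GA	GC	nonCBC
GA	GG	nonCBC
GA	GU	nonCBC
GA	UA	nonCBC
GA	UC	nonCBC
GA	UG	nonCBC
GA	UU	nonCBC
GC	AA	nonCBC
GC	AC	hCBC
GC	AG	nonCBC
GC	AU	CBC
GC	CA	combined
GC	CC	nonCBC
GC	CG	CBC
GC	CU	nonCBC
GC	GA	nonCBC
GC	GC	identical
GC	GG	nonCBC
GC	GU	hCBC
GC	UA	CBC
GC	UC	nonCBC
GC	UG	combined
GC	UU	nonCBC
GG	AA	nonCBC
GG	AC	nonCBC
GG	AG	nonCBC
GG	AU	nonCBC
GG	CA	nonCBC
GG	CC	nonCBC
GG	CG	nonCBC
GG	CU	nonCBC
GG	GA	nonCBC
GG	GC	nonCBC
GG	GG	identical
GG	GU	nonCBC
GG	UA	nonCBC
GG	UC	nonCBC
GG	UG	nonCBC
GG	UU	nonCBC
GU	AA	nonCBC
GU	AC	combined
GU	AG	nonCBC
GU	AU	hCBC
GU	CA	combined
GU	CC	nonCBC
GU	CG	combined
GU	CU	nonCBC
GU	GA	nonCBC
GU	GC	hCBC
GU	GG	nonCBC
GU	GU	identical
GU	UA	combined
GU	UC	nonCBC
GU	UG	combined
GU	UU	nonCBC
UA	AA	nonCBC
UA	AC	combined
UA	AG	nonCBC
UA	AU	CBC
UA	CA	hCBC
UA	CC	nonCBC
UA	CG	CBC
UA	CU	nonCBC
UA	GA	nonCBC
UA	GC	CBC
UA	GG	nonCBC
UA	GU	combined
UA	UA	identical
UA	UC	nonCBC
UA	UG	hCBC
UA	UU	nonCBC
UC	AA	nonCBC
UC	AC	nonCBC
UC	AG	nonCBC
UC	AU	nonCBC
UC	CA	nonCBC
UC	CC	nonCBC
UC	CG	nonCBC
UC	CU	nonCBC
UC	GA	nonCBC
UC	GC	nonCBC
UC	GG	nonCBC
UC	GU	nonCBC
UC	UA	nonCBC
UC	UC	identical
UC	UG	nonCBC
UC	UU	nonCBC
UG	AA	nonCBC
UG	AC	combined
UG	AG	nonCBC
UG	AU	combined
UG	CA	combined
UG	CC	nonCBC
UG	CG	hCBC
UG	CU	nonCBC
UG	GA	nonCBC
UG	GC	combined
UG	GG	nonCBC
UG	GU	combined
UG	UA	hCBC
UG	UC	nonCBC
UG	UG	identical
UG	UU	nonCBC
UU	AA	nonCBC
UU	AC	nonCBC
UU	AG	nonCBC
UU	AU	nonCBC
UU	CA	nonCBC
UU	CC	nonCBC
UU	CG	nonCBC
UU	CU	nonCBC
UU	GA	nonCBC
UU	GC	nonCBC
UU	GG	nonCBC
UU	GU	nonCBC
UU	UA	nonCBC
UU	UC	nonCBC
UU	UG	nonCBC
UU	UU	identical
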