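site_id	matrix	mmhg	thg	ihg
natural	water	0.10		1.62
flooded	water	0.12		1.25
wetland	water	0.23		0.76
natural	periphyton	3.4		23.3
flooded	periphyton	6.7		30.5
wetland	periphyton	2.7		21.7
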