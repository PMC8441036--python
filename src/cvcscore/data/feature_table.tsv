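symbol	ipa	class	voicing	place	manner	height	advancement	rounding	tenseness
P	p	consonant	voiceless	bilabial	stop
B	b	consonant	voiced	bilabial	stop
M	m	consonant	voiced	bilabial	nasal
W	w	consonant	voiced	bilabial	glide
F	f	consonant	voiceless	labio-dental	fricative
V	v	consonant	voiced	labio-dental	fricative
TH	θ	consonant	voiceless	dental	fricative
DH	ð	consonant	voiced	dental	fricative
T	t	consonant	voiceless	alveolar	stop
D	d	consonant	voiced	alveolar	stop
S	s	consonant	voiceless	alveolar	fricative
Z	z	consonant	voiced	alveolar	fricative
N	n	consonant	voiced	alveolar	nasal
L	l	consonant	voiced	alveolar	liquid
R	r	consonant	voiced	palatal	liquid
SH	ʃ	consonant	voiceless	palatal	fricative
ZH	ʒ	consonant	voiced	palatal	fricative
CH	tʃ	consonant	voiceless	palatal	affricate
JH	dʒ	consonant	voiced	palatal	affricate
Y	j	consonant	voiced	palatal	glide
K	k	consonant	voiceless	velar	stop
G	g	consonant	voiced	velar	stop
NG	ŋ	consonant	voiced	velar	nasal
HH	h	consonant	voiceless	glottal	fricative
IY	i	vowel				high	front	unrounded	tense
IH	ɪ	vowel				high	front	unrounded	lax
EY	e	vowel				mid	front	unrounded	tense
EH	ɛ	vowel				mid	front	unrounded	lax
AE	ae	vowel				low	front	unrounded	lax
AA	ɑ	vowel				low	back	unrounded	tense
AO	ɔ	vowel				low	back	rounded	tense
AH	ʌ	vowel				mid	central	unrounded	lax
ER	ɝ	vowel				mid	central	unrounded	tense
UW	u	vowel				high	back	rounded	tense
UH	ʊ	vowel				high	back	rounded	lax
OW	o	vowel				mid	back	rounded	tense
AY	aɪ	vowel				low	central	unrounded	tense
AW	aʊ	vowel				low	central	unrounded	tense
OY	ɔɪ	vowel				mid	back	rounded	tense
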