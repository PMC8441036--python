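word	transcription
bat	B AE T
cake	K EY K
dog	D AO G
fish	F IH SH
cup	K AH P
ball	B AO L
bed	B EH D
sun	S AH N
pig	P IH G
book	B UH K
boat	B OW T
map	M AE P
net	N EH T
bug	B AH G
sock	S AA K
kite	K AY T
leg	L EH G
moon	M UW N
web	W EH B
dish	D IH SH
hat	HH AE T
van	V AE N
goat	G OW T
sheep	SH IY P
nut	N AH T
top	T AA P
zip	Z IH P
pot	P AA T
duck	D AH K
feet	F IY T
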