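surface_form	normalized_name	category	term_type
heroin	Heroin	heroin	generic
diacetylmorphine	Heroin	heroin	generic
diamorphine	Heroin	heroin	generic
dope	Heroin	heroin	slang
smack	Heroin	heroin	slang
skag	Heroin	heroin	slang
junk	Heroin	heroin	slang
horse	Heroin	heroin	slang
tar	Heroin	heroin	slang
china white	Heroin	heroin	street
black tar	Heroin	heroin	street
brown sugar	Heroin	heroin	street
mexican brown	Heroin	heroin	street
dog food	Heroin	heroin	street
number 4	Heroin	heroin	street
U-47700	U-47700	synthetic_heroin	generic
U47700	U-47700	synthetic_heroin	abbreviation
u47	U-47700	synthetic_heroin	abbreviation
pink	U-47700	synthetic_heroin	street
pinky	U-47700	synthetic_heroin	street
U-50488	U-50488	synthetic_heroin	generic
U-49900	U-49900	synthetic_heroin	generic
U-48800	U-48800	synthetic_heroin	generic
U-4TDP	U-4TDP	synthetic_heroin	generic
MT-45	MT-45	synthetic_heroin	generic
AH-7921	AH-7921	synthetic_heroin	generic
W-18	W-18	synthetic_heroin	generic
MPF-47700	MPF-47700	synthetic_heroin	generic
synthetic heroin	Synthetic heroin	synthetic_heroin	common
Duragesic	Fentanyl (pharmaceutical)	pharmaceutical_fentanyl	brand
Sublimaze	Fentanyl (pharmaceutical)	pharmaceutical_fentanyl	brand
Actiq	Fentanyl (pharmaceutical)	pharmaceutical_fentanyl	brand
Fentora	Fentanyl (pharmaceutical)	pharmaceutical_fentanyl	brand
Abstral	Fentanyl (pharmaceutical)	pharmaceutical_fentanyl	brand
Subsys	Fentanyl (pharmaceutical)	pharmaceutical_fentanyl	brand
Lazanda	Fentanyl (pharmaceutical)	pharmaceutical_fentanyl	brand
Ionsys	Fentanyl (pharmaceutical)	pharmaceutical_fentanyl	brand
fentanyl transdermal system	Fentanyl (pharmaceutical)	pharmaceutical_fentanyl	marketing
fentanyl patch	Fentanyl (pharmaceutical)	pharmaceutical_fentanyl	common
fentanyl lollipop	Fentanyl (pharmaceutical)	pharmaceutical_fentanyl	common
carfentanil	Carfentanil	nonpharmaceutical_fentanyl	generic
acetylfentanyl	Acetylfentanyl	nonpharmaceutical_fentanyl	generic
acetyl fentanyl	Acetylfentanyl	nonpharmaceutical_fentanyl	common
acrylfentanyl	Acrylfentanyl	nonpharmaceutical_fentanyl	generic
furanylfentanyl	Furanylfentanyl	nonpharmaceutical_fentanyl	generic
furanyl fentanyl	Furanylfentanyl	nonpharmaceutical_fentanyl	common
butyrfentanyl	Butyrfentanyl	nonpharmaceutical_fentanyl	generic
butryfentanyl	Butyrfentanyl	nonpharmaceutical_fentanyl	common
methoxyacetylfentanyl	Methoxyacetylfentanyl	nonpharmaceutical_fentanyl	generic
fluorofentanyl	Fluorofentanyl	nonpharmaceutical_fentanyl	generic
benzylfentanyl	Benzylfentanyl	nonpharmaceutical_fentanyl	generic
betahydroxyfentanyl	Betahydroxyfentanyl	nonpharmaceutical_fentanyl	generic
betamethylfentanyl	Betamethylfentanyl	nonpharmaceutical_fentanyl	generic
methylfentanyl	Methylfentanyl	nonpharmaceutical_fentanyl	generic
crotonylfentanyl	Crotonylfentanyl	nonpharmaceutical_fentanyl	generic
isobutyrfentanyl	Isobutyrfentanyl	nonpharmaceutical_fentanyl	generic
lofentanyl	Lofentanyl	nonpharmaceutical_fentanyl	generic
etorphine	Etorphine	nonpharmaceutical_fentanyl	generic
china girl	Fentanyl (nonpharmaceutical)	nonpharmaceutical_fentanyl	street
fentanyl	Fentanyl	fentanyl	generic
fent	Fentanyl	fentanyl	slang
fenty	Fentanyl	fentanyl	slang
fetty	Fentanyl	fentanyl	slang
fen	Fentanyl	fentanyl	abbreviation
apache	Fentanyl	fentanyl	street
murder 8	Fentanyl	fentanyl	street
dance fever	Fentanyl	fentanyl	street
goodfella	Fentanyl	fentanyl	street
jackpot	Fentanyl	fentanyl	street
oxycodone	Oxycodone	oxycodone	generic
oxycodone hydrochloride	Oxycodone	oxycodone	generic
oxy	Oxycodone	oxycodone	slang
oxys	Oxycodone	oxycodone	slang
roxy	Oxycodone	oxycodone	slang
roxies	Oxycodone	oxycodone	slang
percs	Oxycodone	oxycodone	slang
OxyContin	Oxycodone	oxycodone	brand
Percocet	Oxycodone	oxycodone	brand
Roxicodone	Oxycodone	oxycodone	brand
Oxaydo	Oxycodone	oxycodone	brand
Xtampza	Oxycodone	oxycodone	brand
hillbilly heroin	Oxycodone	oxycodone	street
kicker	Oxycodone	oxycodone	street
oxycotton	Oxycodone	oxycodone	street
kratom	Kratom	kratom	generic
mitragyna speciosa	Kratom	kratom	generic
mitragynine	Kratom	kratom	generic
maeng da	Kratom	kratom	marketing
red bali	Kratom	kratom	marketing
green malay	Kratom	kratom	marketing
white borneo	Kratom	kratom	marketing
ketum	Kratom	kratom	common
biak-biak	Kratom	kratom	common
kakuam	Kratom	kratom	common
thom	Kratom	kratom	common
opium	Opium	opium	generic
opium tincture	Opium	opium	generic
laudanum	Opium	opium	generic
paregoric	Opium	opium	generic
poppy	Opium	opium	common
poppy tea	Opium	opium	common
poppy pod	Opium	opium	common
midnight oil	Opium	opium	street
pen yan	Opium	opium	street
chandu	Opium	opium	street
aunti	Opium	opium	street
big o	Opium	opium	street
gum	Opium	opium	slang
dopium	Opium	opium	slang
chinese molasses	Opium	opium	street
dreamer	Opium	opium	slang
zero	Opium	opium	street
toxy	Opium	opium	slang
toys	Opium	opium	slang
midnight special	Opium	opium	street
god's medicine	Opium	opium	street
guma	Opium	opium	street
pox	Opium	opium	slang
black stuff	Opium	opium	street
block	Opium	opium	street
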