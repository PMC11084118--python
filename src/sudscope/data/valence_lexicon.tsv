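token	valence
good	1.9
great	3.1
love	3.2
loved	2.9
happy	2.7
awesome	3.1
amazing	2.8
wonderful	2.7
fantastic	2.6
excellent	2.7
relief	1.9
relieved	2.1
clean	1.6
hope	1.9
hopeful	2.3
thankful	2.7
thanks	1.9
grateful	3.0
gratitude	2.6
better	1.9
best	3.2
calm	1.3
excited	2.3
joy	2.8
joyful	2.9
peace	2.5
peaceful	2.4
proud	2.2
safe	1.8
sober	1.5
sobriety	1.7
strong	2.3
win	2.8
winning	2.4
support	1.7
supportive	2.0
help	1.7
helpful	1.9
helped	1.8
free	1.7
freedom	2.3
smile	2.1
blessed	2.9
recovery	1.6
recovered	1.9
healing	2.0
energy	1.1
comfortable	1.5
easy	1.2
fine	0.8
okay	0.9
nice	1.8
glad	2.0
enjoy	2.2
surprise	1.1
surprised	0.9
bad	-2.5
awful	-3.1
terrible	-3.1
horrible	-3.0
pain	-2.3
painful	-2.6
hurt	-2.4
hurts	-2.4
sick	-2.3
sad	-2.1
sadness	-2.2
fear	-2.2
afraid	-2.2
scared	-2.2
scary	-2.1
terrified	-3.0
anxious	-1.9
anxiety	-2.0
depressed	-2.8
depression	-2.6
withdrawal	-2.1
withdrawals	-2.1
craving	-1.4
cravings	-1.4
hate	-2.7
hated	-2.6
worst	-3.1
die	-3.3
dying	-3.1
dead	-3.0
death	-2.9
alone	-1.6
lonely	-2.1
cry	-2.0
crying	-2.2
lost	-1.3
nausea	-2.0
nauseous	-2.0
vomiting	-2.4
shaking	-1.2
shakes	-1.1
sweats	-1.2
relapse	-2.5
relapsed	-2.6
overdose	-3.2
overdosed	-3.3
hopeless	-3.0
miserable	-2.9
suffering	-2.8
suffer	-2.6
angry	-2.3
anger	-2.2
furious	-2.9
rage	-2.5
panic	-2.4
tired	-1.2
exhausted	-1.8
broke	-1.9
broken	-2.2
trouble	-1.9
struggle	-1.9
struggling	-2.0
desperate	-2.4
numb	-1.5
empty	-1.4
worthless	-2.9
ashamed	-2.4
shame	-2.3
guilty	-2.1
guilt	-2.1
wreck	-2.2
nightmare	-2.7
insomnia	-1.8
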