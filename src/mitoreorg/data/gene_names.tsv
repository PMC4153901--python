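# Gene-name normalization table, version 1.
# alias (case-insensitive) <TAB> normalized MitoZoa-style token
# Ambiguous tRNA-Leu / tRNA-Ser aliases map to the base token and are
# disambiguated from the anticodon or an explicit (UUR)/(CUN)/(UCN)/(AGY)
# tag by the reader.
cox1	cox1
coxi	cox1
coi	cox1
co1	cox1
mt-co1	cox1
cox2	cox2
coxii	cox2
coii	cox2
co2	cox2
mt-co2	cox2
cox3	cox3
coxiii	cox3
coiii	cox3
co3	cox3
mt-co3	cox3
cob	cob
cytb	cob
cyt b	cob
mt-cyb	cob
cytochrome b	cob
nad1	nad1
nd1	nad1
mt-nd1	nad1
nad2	nad2
nd2	nad2
mt-nd2	nad2
nad3	nad3
nd3	nad3
mt-nd3	nad3
nad4	nad4
nd4	nad4
mt-nd4	nad4
nad4l	nad4L
nd4l	nad4L
mt-nd4l	nad4L
nad5	nad5
nd5	nad5
mt-nd5	nad5
nad6	nad6
nd6	nad6
mt-nd6	nad6
atp6	atp6
atpase6	atp6
atpase 6	atp6
mt-atp6	atp6
atp8	atp8
atpase8	atp8
atpase 8	atp8
mt-atp8	atp8
rrns	rrnS
12s	rrnS
12s rrna	rrnS
12s ribosomal rna	rrnS
s-rrna	rrnS
small subunit ribosomal rna	rrnS
mt-rnr1	rrnS
rrnl	rrnL
16s	rrnL
16s rrna	rrnL
16s ribosomal rna	rrnL
l-rrna	rrnL
large subunit ribosomal rna	rrnL
mt-rnr2	rrnL
cr	CR
d-loop	CR
control region	CR
misc_feature	CR
ol	OL
oril	OL
rep_origin	OL
origin of l-strand replication	OL
l-strand origin	OL
light strand origin	OL
trnf	trnF
trna-phe	trnF
trnv	trnV
trna-val	trnV
trnl	trnL
trna-leu	trnL
trnl(uur)	trnL(UUR)
trnl(cun)	trnL(CUN)
trni	trnI
trna-ile	trnI
trnq	trnQ
trna-gln	trnQ
trnm	trnM
trna-met	trnM
trnw	trnW
trna-trp	trnW
trna	trnA
trna-ala	trnA
trnn	trnN
trna-asn	trnN
trnc	trnC
trna-cys	trnC
trny	trnY
trna-tyr	trnY
trns	trnS
trna-ser	trnS
trns(ucn)	trnS(UCN)
trns(agy)	trnS(AGY)
trnd	trnD
trna-asp	trnD
trnk	trnK
trna-lys	trnK
trng	trnG
trna-gly	trnG
trnr	trnR
trna-arg	trnR
trnh	trnH
trna-his	trnH
trne	trnE
trna-glu	trnE
trnt	trnT
trna-thr	trnT
trnp	trnP
trna-pro	trnP
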