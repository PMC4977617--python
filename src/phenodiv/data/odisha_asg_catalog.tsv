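# Qualitative descriptor catalogue for the Odisha aromatic short-grain (ASG)
# rice landrace panel: 24 traits, 70 variables. Variable codes give the global
# column order used by the binary encoding and the phenoprint barcodes.
trait_key	trait_name	variable_code	variable_label
BLS	Basal leaf sheath colour	1	Green
BLS	Basal leaf sheath colour	2	Light purple
BLS	Basal leaf sheath colour	3	Purple lines
BLS	Basal leaf sheath colour	4	Purple
FLA	Flag leaf attitude of blade	5	Erect
FLA	Flag leaf attitude of blade	6	Semi erect
FLA	Flag leaf attitude of blade	7	Horizontal
FLA	Flag leaf attitude of blade	8	Deflexed
CA	Culm angle	9	Erect
CA	Culm angle	10	Semi erect
ST	Stem thickness	11	Weak
ST	Stem thickness	12	Medium
ST	Stem thickness	13	Strong
PA	Panicle: awns	14	Absent
PA	Panicle: awns	15	Present
PCA	Panicle: colour of awns	16	Yellowish white
PCA	Panicle: colour of awns	17	Light red
PCA	Panicle: colour of awns	18	Purple
PCA	Panicle: colour of awns	19	Black
PMA	Panicle: curvature of main axis	20	Straight
PMA	Panicle: curvature of main axis	21	Dropping
SCL	Spikelet: tip colour of lemma	22	White
SCL	Spikelet: tip colour of lemma	23	Yellowish
SCL	Spikelet: tip colour of lemma	24	Brown
SCL	Spikelet: tip colour of lemma	25	Red
SCL	Spikelet: tip colour of lemma	26	Purple
SCL	Spikelet: tip colour of lemma	27	Black
PE	Panicle exertion	28	Partly exserted
PE	Panicle exertion	29	Exserted
PE	Panicle exertion	30	Well exserted
LI	Leaf intensity of blade colour	31	Medium
LA	Leaf: anthocyanin colour	32	Absent
LPB	Leaf: pubescence of blade surface	33	Medium
LL	Leaf: ligule	34	Present
CL	Leaf: colour of ligule	35	Green
LSL	Leaf: shape of ligule	36	Truncate
LSL	Leaf: shape of ligule	37	Acute
LSL	Leaf: shape of ligule	38	Split
LAR	Leaf: auricles	39	Absent
LAR	Leaf: auricles	40	Present
CSTG	Spikelet: colour of stigma	41	White
CSTG	Spikelet: colour of stigma	42	Yellow
CSTG	Spikelet: colour of stigma	43	Light purple
CSTG	Spikelet: colour of stigma	44	Purple
PAB	Panicle: attitude of branches	45	Erect
PAB	Panicle: attitude of branches	46	Semierect
PAB	Panicle: attitude of branches	47	Semierect to spreading
PAB	Panicle: attitude of branches	48	Spreading
CC	Collar colour	49	Pale green
INC	Internode colour	50	Green
INC	Internode colour	51	Light gold
INC	Internode colour	52	Purple line
PSB	Panicle secondary branching	53	Weak
PSB	Panicle secondary branching	54	Strong
LAG	Leaf angle	55	Erect
LAG	Leaf angle	56	Semi erect
LAG	Leaf angle	57	Horizontal
LAG	Leaf angle	58	Droopy
LPC	Lemma palea colour	59	Straw
LPC	Lemma palea colour	60	Brown Furrow
LPC	Lemma palea colour	61	Brown
LPC	Lemma palea colour	62	Red
LPC	Lemma palea colour	63	Purple
LPC	Lemma palea colour	64	Purple Furrow
LPC	Lemma palea colour	65	Black
LPC	Lemma palea colour	66	Brown Spot
GT	Grain type	67	Short bold
GT	Grain type	68	Medium bold
GT	Grain type	69	Medium slender
GT	Grain type	70	Medium long
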