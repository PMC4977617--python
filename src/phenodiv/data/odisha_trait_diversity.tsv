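# Published per-trait diversity statistics for the 126-genotype Odisha ASG
# rice panel (values as printed, 3 decimals). Na = observed state count,
# Ne = effective state number, He = Nei gene diversity, I = Shannon index.
trait_key	Na	Ne	He	I
BLS	4	2.590	0.614	1.098
FLA	4	2.886	0.653	1.140
CA	2	1.016	0.016	0.046
ST	3	2.477	0.596	0.999
PA	2	1.190	0.159	0.296
PCA	4	1.196	0.164	0.387
PMA	2	1.190	0.159	0.296
SCL	6	3.065	0.674	1.273
PE	3	1.609	0.379	0.656
LI	1	1.000	0.000	0.000
LA	1	1.000	0.000	0.000
LPB	1	1.000	0.000	0.000
LL	1	1.000	0.000	0.000
CL	1	1.000	0.000	0.000
LSL	3	1.101	0.091	0.213
LAR	2	1.016	0.016	0.046
CSTG	4	1.751	0.429	0.841
PAB	4	1.335	0.251	0.490
CC	1	1.000	0.000	0.000
INC	3	1.766	0.434	0.739
PSB	2	1.864	0.464	0.656
LAG	4	2.161	0.537	0.859
LPC	8	3.292	0.696	1.518
GT	4	2.094	0.522	0.804
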