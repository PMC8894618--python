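# Worked-example animal DEG table: domestic-vs-wild differential expression
# observations.  log2fc is expression in the domesticated (or tame) animal
# relative to the wild (or aggressive) congener, in log2 units; the
# significance call is the source study's.  Rows whose magnitude (and, where
# flagged, sign) is not stated verbatim in the narrative carry a note; such
# magnitudes are synthetic and only the sign enters the analysis.
symbol	domestic_taxon	wild_taxon	tissue	log2fc	pvalue	source	note
Ckbl	Canis familiaris	Canis lupus	blood	4.33	1e-05	Yang X. et al., 2018
Adm	Canis familiaris	Canis lupus	frontal cortex	-1.55	0.001	Albert et al., 2012
Hpd	Vulpes vulpes (tame)	Vulpes vulpes (aggressive)	pituitary gland	-0.47	0.02	Hekman et al., 2018
Mdk	Sus scrofa domesticus	Sus scrofa	frontal cortex	0.92	0.005	Albert et al., 2012	sign from narrative; synthetic magnitude
C7	Sus scrofa domesticus	Sus scrofa	frontal cortex	1.08	0.003	Long et al., 2018	sign from narrative; synthetic magnitude
Ano3	Sus scrofa domesticus	Sus scrofa	pituitary gland	-1.32	0.01	Yang Y. et al., 2018
Agt	Cavia porcellus	Cavia aperea	frontal cortex	-0.84	0.02	Albert et al., 2012	sign from narrative; synthetic magnitude
Gp2	Sus scrofa domesticus	Sus scrofa	pituitary gland	0.66	0.03	Yang Y. et al., 2018	synthetic sign and magnitude
ApoD	Canis familiaris	Canis lupus	blood	-0.58	0.04	Yang X. et al., 2018	synthetic sign and magnitude
Pgk1	Gallus gallus domesticus	Gallus gallus	pituitary gland	0.71	0.02	Fallahshahroudi et al., 2019	synthetic sign and magnitude
Aqp1	Oryctolagus cuniculus domesticus	Oryctolagus cuniculus	frontal cortex	-0.63	0.03	Albert et al., 2012	synthetic sign and magnitude
Irf6	Vulpes vulpes (tame)	Vulpes vulpes (aggressive)	pituitary gland	0.52	0.04	Hekman et al., 2018	synthetic sign and magnitude
Alb	Cavia porcellus	Cavia aperea	frontal cortex	-0.77	0.02	Albert et al., 2012	synthetic sign and magnitude
Fst	Gallus gallus domesticus	Gallus gallus	pituitary gland	0.59	0.03	Fallahshahroudi et al., 2019	synthetic sign and magnitude
Apoa1	Cavia porcellus	Cavia aperea	frontal cortex	-3.2	0.001	Albert et al., 2012
Cetp	Cavia porcellus	Cavia aperea	frontal cortex	1.9	0.002	Albert et al., 2012	sign from narrative (domestic excess); synthetic magnitude
Cyp17a1	Cavia porcellus	Cavia aperea	frontal cortex	-1.4	0.004	Albert et al., 2012	sign from narrative (domestic deficiency); synthetic magnitude
Cyp17a1	Gallus gallus domesticus	Gallus gallus	pituitary gland	1.2	0.006	Fallahshahroudi et al., 2019	sign from narrative (wild deficiency); synthetic magnitude
Gcg	Cavia porcellus	Cavia aperea	frontal cortex	1.6	0.003	Albert et al., 2012	sign from narrative; synthetic magnitude
Il1b	Cavia porcellus	Cavia aperea	frontal cortex	0.9	0.01	Albert et al., 2012	narrative ambiguous on sign; sign chosen to reproduce the printed marginals
Nr5a1	Cavia porcellus	Cavia aperea	frontal cortex	-1.1	0.008	Albert et al., 2012	sign from narrative; synthetic magnitude
Proc	Cavia porcellus	Cavia aperea	frontal cortex	1.3	0.005	Albert et al., 2012	sign from narrative (domestic excess); synthetic magnitude
F7	Oryctolagus cuniculus domesticus	Oryctolagus cuniculus	frontal cortex	-0.95	0.01	Albert et al., 2012	sign from narrative (wild excess); synthetic magnitude
F3	Gallus gallus domesticus	Gallus gallus	pituitary gland	1.05	0.007	Fallahshahroudi et al., 2019	sign from narrative (domestic excess); synthetic magnitude
Gh1	Canis familiaris	Canis lupus	blood	2.1	0.002	Yang X. et al., 2018	sign from narrative (domestic excess); synthetic magnitude
Hba1	Canis familiaris	Canis lupus	blood	-1.8	0.005	Yang X. et al., 2018	sign from narrative (domestic hemoglobin deficiency); synthetic magnitude
Hbbl	Canis familiaris	Canis lupus	blood	-2.3	0.004	Yang X. et al., 2018	sign from narrative (domestic hemoglobin deficiency); synthetic magnitude
Hbm	Canis familiaris	Canis lupus	blood	-1.2	0.006	Yang X. et al., 2018	sign from narrative (domestic hemoglobin deficiency); synthetic magnitude
Hbad	Gallus gallus domesticus	Gallus gallus	pituitary gland	-0.9	0.009	Fallahshahroudi et al., 2019	sign from narrative (domestic hemoglobin deficiency); synthetic magnitude
Hbz1	Gallus gallus domesticus	Gallus gallus	pituitary gland	-1.0	0.008	Fallahshahroudi et al., 2019	sign from narrative (domestic hemoglobin deficiency); synthetic magnitude
Esr2	Vulpes vulpes (tame)	Vulpes vulpes (aggressive)	pituitary gland	-0.6	0.03	Hekman et al., 2018	narrative leaves sign open; both human directions harmful, so counts are sign-invariant
Il9r	Vulpes vulpes (tame)	Vulpes vulpes (aggressive)	pituitary gland	0.8	0.02	Hekman et al., 2018	sign from narrative (tame excess); synthetic magnitude
Pgr	Gallus gallus domesticus	Gallus gallus	pituitary gland	1.4	0.004	Fallahshahroudi et al., 2019	sign from narrative (wild deficiency); synthetic magnitude
Slc25a6	Gallus gallus domesticus	Gallus gallus	pituitary gland	1.1	0.006	Fallahshahroudi et al., 2019	sign from narrative (domestic excess); synthetic magnitude
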