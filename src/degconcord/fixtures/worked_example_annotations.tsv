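# Worked-example human gene annotations: per-direction effect of an
# expression change on human reproductive potential, with the clinical or
# model-organism evidence behind each call.  This is the subset of the
# curated 68-gene knowledge base whose directions are stated in the
# published narrative; the hemoglobin-overexpression effect (INCREASE) is
# the direction consistent with the printed 2x2 marginals.
symbol	effect_under	effect_over	evidence
APOA1	decrease	decrease	Peng et al., 2017 (cognitive disorders); Manohar et al., 2014 (infertility in women)
CETP	increase	decrease	Plengpanich et al., 2011 (slowed atherogenesis); Silliman et al., 1993 (hypercholesterolemia of pregnancy)
CYP17A1	decrease	increase	Marsh, Auchus, 2014 (impaired fertility); Nna et al., 2020 (overcomes subfertility)
GCG	decrease	decrease	Sugiyama et al., 2012; Sun et al., 2019 (reduced pregnancy rate at both extremes)
IL1B	increase	decrease	Sasaki et al., 2020 (bone protection); Olkkonen et al., 2015 (circadian pain sensitivity)
NR5A1	decrease	increase	Nagaraja et al., 2019 (gonadal dysgenesis); Wood et al., 2011 (improved sperm quality)
PROC	decrease	decrease	Dinarvand, Moser, 2019 (purpura fulminans); Lay et al., 2005 (miscarriage risk)
F7	decrease	increase	Senol, Zulfikar, 2020 (life-threatening bleeding); Burad et al., 2012 (rescue of obstetric bleeding)
F3	increase	decrease	Yu et al., 2020; Arnaud et al., 2000 (stroke and myocardial infarction)
GH1	decrease	increase	Jorgensen, Juul, 2018 (cardiovascular mortality); Regan et al., 2018 (raises reproductive potential of women)
HBB	decrease	increase	Takhviji et al., 2020 (thalassemia lowers reproductive potential)
HBD	decrease	increase	Takhviji et al., 2020 (thalassemia lowers reproductive potential)
ESR2	decrease	decrease	Ivanski et al., 2020 (reduced sperm quality at both extremes)
IL9R	decrease	decrease	Sun et al., 2020 (disrupted trophoblast implantation); Osterfeld et al., 2010 (anaphylactic shock)
PGR	decrease	increase	Kubota et al., 2016 (infertility in knockout model); Yao et al., 2020 (positive fertility correlation)
SLC25A6	decrease	increase	Clemencon et al., 2013 (muscle dystrophy risk); Guo et al., 2015 (herpes-virus resistance)
ACKR1	decrease	decrease	Michon et al., 2001; Hernandez-Aguilera et al., 2020 (coronary-disease mortality)
DNMT1	increase	decrease	Awada et al., 2020 (decitabine-like reduction); Matrisciano et al., 2013 (fetal-brain epigenetic aberrations)
PLCXD1	decrease	increase	Tian et al., 2012 (stroke risk in men); Mithani et al., 2011 (melanoma suppression)
ZFY	decrease	decrease	curated: both underexpression and overexpression impair the reproductive system
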