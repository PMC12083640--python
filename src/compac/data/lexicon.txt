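# Default COMPAC value sets and lexicons.
#
# Sections are introduced by "[NAME]".  Lines starting with "#" and blank
# lines are ignored, except inside medication sections where blank lines
# separate drug families (generic + brand names of one product family).
#
# Diagnosis sections hold code prefixes (dot-insensitive).  Keyword sections
# hold one phrase per line; phrases are matched case-insensitively with word
# boundaries, internal whitespace matching any run of whitespace.

[DX:ICD9CM]
493

[DX:ICD10CM]
J45

[BDR]
albuterol
albuterol sulfate
ventolin
proventil
proair
accuneb
vospire er

ipratropium bromide
atrovent

levalbuterol
xopenex hfa

metaproterenol
alupent

pirbuterol
maxair

terbutaline
brethine

[ICS]
beclomethasone propionate
qvar

budesonide
pulmicort turbuhaler
pulmicort flexhaler
pulmicort respules

ciclesonide
alvesco

flunisolide
aerobid
aerobid-m
aerospan 80

fluticasone propionate
flovent hfa
flovent diskus

mometasone
asmanex hfa
asmanex twisthaler

triamcinolone acetonide
azmacort

[KW1]
bronchospasm
bronchospastic cough
exercise-induced wheezing
exercise-induced asthma
asthma
asthma flare
asthma attack
asthma exacerbation
reactive airway disease
RAD
asthma action plan
asthma control plan
pulmonology referral for asthma
allergy referral for asthma
pulmonary function tests confirm asthma
PFTs confirm asthma
spirometry confirm asthma

[KW2]
wheezing
dyspnea
shortness of breath
SOB
nighttime cough
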