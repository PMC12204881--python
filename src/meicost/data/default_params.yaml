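# Default input parameter set of the lifetime-cost simulation model.
# Scalar inputs are fixed model values; distribution entries are the
# pre-fitted input distributions of the stochastic symbols.
lex: 81          # life expectancy, years
mia: 5           # minimum implantation age, years
discount_rate: 0.05
foa: 145         # flat-rate outpatient appointment, EUR
apu: 5719.9      # audio processor price, EUR
ttua: 6          # minimum reimbursable time to processor upgrade, years

afi:             # age at first intervention (AFIa/b/c are i.i.d. draws)
  family: weibull3
  params: {shape: 244.32323, scale: 2866.73542, threshold: -2806.08613}
isb:             # middle-ear implant (incl. surgery) inpatient cost, EUR
  family: lognormal
  params: {location: 9.57283, scale: 0.07429}
lts:             # implant lifetime, years (negatives floored by the model)
  family: triangular
  params: {lower: -3, mode: 0, upper: 400}
ttr:             # time to revision, years (negatives floored by the model)
  family: triangular
  params: {lower: -3, mode: 0, upper: 140}
rev:             # revision inpatient cost, EUR
  family: lognormal
  params: {location: 8.29047, scale: 0.20121}
ttub:            # additional time to upgrade beyond the 6-year minimum, years
  family: exponential_shifted
  params: {rate: 1.41988, shift: 0}
thit:            # total time under surgical management before implant, years
  family: lognormal
  params: {location: 0.70939, scale: 1.3453}
dsh:             # duration of success of one hearing-improvement surgery, years
  family: weibull3
  params: {shape: 0.68361, scale: 1.74601, threshold: 0.28273}
his:             # hearing-improvement surgery inpatient cost, EUR
  family: lognormal
  params: {location: 8.2339, scale: 0.25662}

max_reimplantations: 2
max_revisions: 3
max_upgrades: 12
max_surgeries_g2: 6     # incl. initial surgery
max_surgeries_g3: 15    # incl. initial surgery
thi_cap: 25             # years under surgical management before implant, group 2
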