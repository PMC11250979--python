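# Default misspecification sensitivity grid for the inclusion model.
#
# Each entry perturbs one log-scale coefficient of the inclusion model by an
# additive delta at three levels: 50% (mild), 100% (the discrepancy suggested
# by comparing the national evidence with local catchment data) and 200%
# (extreme, akin to Greater-London-level discrepancies). Entries marked
# `companion: true` are applied together with a 100% downward shift of the
# death main effect (lg1 - 0.15); without it, raising a survivor-stratum
# coefficient would push died-stratum probabilities above 1.
#
# The `eq1` block applies to both model forms; the `eq2_extra` block adds the
# wave-related coefficients and applies only to the two-wave model.
# Unknown-ethnicity coefficients are never shifted.
companion_deltas:
  lg1: -0.15
eq1:
  lg0:          {companion: false, deltas: {50: -0.05,  100: -0.1,  200: -0.2}}
  lg1:          {companion: false, deltas: {50: -0.075, 100: -0.15, 200: -0.3}}
  "la[Black]":       {companion: true,  deltas: {50: 0.125, 100: 0.25, 200: 0.5}}
  "la[Asian]":       {companion: true,  deltas: {50: 0.125, 100: 0.25, 200: 0.5}}
  "la[Mixed/Other]": {companion: true,  deltas: {50: 0.1,   100: 0.2,  200: 0.4}}
  "lb[Black]":       {companion: false, deltas: {50: -0.1,  100: -0.2, 200: -0.4}}
  "lb[Asian]":       {companion: false, deltas: {50: -0.1,  100: -0.2, 200: -0.4}}
  "lb[Mixed/Other]": {companion: false, deltas: {50: -0.1,  100: -0.2, 200: -0.4}}
eq2_extra:
  lg2:          {companion: true,  deltas: {50: 0.25,  100: 0.5,  200: 1.0}}
  lg3:          {companion: false, deltas: {50: -0.35, 100: -0.7, 200: -1.4}}
  "lc[Black]":       {companion: true,  deltas: {50: 0.125, 100: 0.25, 200: 0.5}}
  "lc[Asian]":       {companion: true,  deltas: {50: -0.1,  100: -0.2, 200: -0.4}}
  "lc[Mixed/Other]": {companion: true,  deltas: {50: 0.125, 100: 0.25, 200: 0.5}}
  "ld[Black]":       {companion: true,  deltas: {50: 0.1,   100: 0.2,  200: 0.4}}
  "ld[Asian]":       {companion: true,  deltas: {50: 0.1,   100: 0.2,  200: 0.4}}
  "ld[Mixed/Other]": {companion: true,  deltas: {50: 0.1,   100: 0.2,  200: 0.4}}
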