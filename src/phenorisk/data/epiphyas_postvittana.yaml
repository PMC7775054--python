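# Light brown apple moth (Epiphyas postvittana) — temperatures in C,
# durations/events/limits in degree-days C. Overwintering stage: late larva.
name: Epiphyas postvittana
units: C
owstage: larvae

eggLDT: 7.2
larvaeLDT: 7.2
pupaeLDT: 7.2
adultLDT: 7.2
eggUDT: 31.1
larvaeUDT: 31.1
pupaeUDT: 31.1
adultUDT: 31.1

eggDD: 127
larvaeDD: 408
pupDD: 128
adultDD: 71

# events: beginning of egg hatch, mid-larval development,
# first adult emergence, first egg laying
eggEventDD: 126
larvaeEventDD: 203
pupaeEventDD: 128
adultEventDD: 22

coldstress_threshold: 3
coldstress_units_max1: 875
coldstress_units_max2: 1125
heatstress_threshold: 31
heatstress_units_max1: 375
heatstress_units_max2: 550

distro_mean: 210
distro_var: 2500
xdist1: 100
xdist2: 320
distro_shape: normal
calctype: triangle
max_event_generations: 4
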