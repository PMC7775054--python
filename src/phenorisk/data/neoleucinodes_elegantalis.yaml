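# Small tomato borer (Neoleucinodes elegantalis) — temperatures in C,
# durations/events/limits in degree-days C. Overwintering stage: adult
# (no true diapause; adults assumed active from the start date).
name: Neoleucinodes elegantalis
units: C
owstage: adults

eggLDT: 8.89
larvaeLDT: 8.89
pupaeLDT: 8.89
adultLDT: 8.89
eggUDT: 30
larvaeUDT: 30
pupaeUDT: 30
adultUDT: 30

eggDD: 86
larvaeDD: 283
pupDD: 203
adultDD: 96

# events: beginning of egg hatch, mid-larval development,
# mid-pupal development, first egg laying
eggEventDD: 80
larvaeEventDD: 140
pupaeEventDD: 100
adultEventDD: 55

coldstress_threshold: 6
coldstress_units_max1: 1150
coldstress_units_max2: 1600
heatstress_threshold: 32
heatstress_units_max1: 750
heatstress_units_max2: 1000

distro_mean: 50
distro_var: 1500
xdist1: 0
xdist2: 111
distro_shape: normal
calctype: triangle
max_event_generations: 4
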