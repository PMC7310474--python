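HUMAN	mammal
MOUSE	mammal
BOVIN	mammal
CHICK	reptile_bird
APTFO	reptile_bird
CHEMY	reptile_bird
PELSI	reptile_bird
XENTR	amphibian
NANPA	amphibian
LATCH	lobe_finned_fish
DANRE	ray_finned_fish
SALSA	ray_finned_fish
LEPOC	ray_finned_fish
SCLFO	ray_finned_fish
NOTKA	ray_finned_fish
9TELE	ray_finned_fish
RHITY	cartilaginous_fish
CALMI	cartilaginous_fish
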