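# Standard planets-and-pirates schedule.
block_duration_s: 180.0
n_pre_blocks: 2
n_punish_blocks: 3
reward_prob: 0.5
reward_points: 100
trade_countdown_s: 2.0
cs_prob: 0.2
cs_delay_s: 1.5
cs_duration_s: 6.0
attack_fraction: 0.2
shield_avail_prob: 0.5
shield_charge_s: 3.0
shield_cost_points: 50
punished_planet: R1
cs_plus_identity: ship_type_I
side_assignment: left
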