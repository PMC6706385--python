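# Control NET scenario: wild-type Markov Na channels, full pump current.
c_node_pf: 1.5
g_na_transient: 650.0
resurgent_fraction: 0.27
g_na_persistent: 8.0
g_k_slow_node: 12.0
g_k_fast_node: 15.0
g_leak_node: 2.0
c_internode_pf: 500.0
g_k_fast_internode: 8.0
g_k_slow_internode: 6.0
g_hcn: 5.0
g_leak_internode: 4.0
g_barrett_barrett: 30.0
e_na: 50.0
e_k: -90.0
e_leak: -85.0
e_hcn: -50.0
pump_current_pa: 30.0
pump_node_fraction: 0.5
temperature_c: 36.0
hh_q10: 2.2
dt_ms: 0.001
channel: wt
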