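name,mu,Qt,Q0,Omega_t,Omega_0,octupole_source,provenance
gas_exp,1.86,2.57,0.11,—,—,gas_qm,reference-tables/multipoles/gas-phase-experimental
gas_qm,1.81,2.49,0.08,1.93,-1.35,,reference-tables/multipoles/gas-phase-QM-CCSD
liquid_mp2_4mm,2.49,2.93,0.13,2.09,-1.73,,reference-tables/multipoles/liquid-phase-MP2-4MM
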