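# Full-scale state-point profiles

These YAML configurations reproduce the cluster-scale low-force studies at
their published statistics (N_t = 1000 trajectories, 2e5 thermalization
steps, 1e8-step budgets).  They are far beyond desk scale; the test suite
asserts the corresponding orderings at reduced statistics instead.  Run one
with

    poretrans ensemble --config configs/<file>.yaml

Note that with the carve-count-calibrated lattice (see docs/methods.md) the
immobile small-pore reference stalls at low force, so the low-f ratio
studies are expected to require the kinetic membrane conditions.
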