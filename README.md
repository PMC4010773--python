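# plinet

Functional brain-network analysis of multichannel scalp EEG built around the
Phase Lag Index (PLI), with classical weighted-graph measures, minimum
spanning tree (MST) topology, and the two-group × two-condition statistics
used in paired clinical designs — plus a coupled-oscillator simulator that
provides ground-truth coupling topologies, so the entire pipeline can be
validated without any clinical data.

The package targets the kind of question asked in pediatric epilepsy
work-ups: when the same child is recorded twice (a routine EEG and an EEG
after sleep deprivation), does the interictal functional network
reorganize, and does it reorganize *differently* in patients than in
controls?

## The method

**Connectivity.** For each pair of electrodes, each epoch and each
frequency band (delta 0.5–4 Hz, theta 4–8 Hz, alpha 8–13 Hz, beta
13–30 Hz), instantaneous phases are taken from the Hilbert analytic signal
of the zero-phase band-filtered trace, and coupling is quantified by the
Phase Lag Index

> PLI = | ⟨ sign(ΔΦ(t_k)) ⟩ |,

the absolute time-average of the sign of the wrapped phase difference.
PLI ∈ [0, 1] is blind to zero-lag (volume-conducted) coupling and to signal
amplitude; epoch-averaged PLI values form the symmetric weight matrix
W = {w_ij} of a 17-node network (the 10-20 montage minus Fp1, Fp2, A1, A2).

**Weighted graph measures.** Segregation is the weighted clustering
coefficient C_i = Σ w_ik w_il w_kl / Σ w_ik w_il (sums over ordered pairs
k ≠ l, both ≠ i); integration is the mean Dijkstra shortest-path length
under reciprocal-weight edge lengths l_ij = 1/w_ij. Both are normalized by
their means over 50 weight-permutation surrogate networks.

**Tree topology.** A maximum spanning tree (Kruskal over descending PLI)
keeps the N − 1 strongest acyclic connections, removing network-density
confounds. Its shape is summarized by the leaf number (degree-1 nodes;
2 … m, m = N − 1) and the hop diameter (2 … m − leaf + 2): a chain has 2
leaves and diameter m, a star m leaves and diameter 2.

**Statistics.** Per group, routine vs sleep-deprived recordings are
compared with paired t-tests. The group-difference-in-change question is
the condition × group interaction of a repeated-measures ANOVA, computed
through the exact 2×2 identity F = t² on per-subject difference scores.
Multiple testing is controlled with Benjamini–Hochberg FDR within each
frequency band.

**Simulation.** Channels are narrowband oscillators whose phases are
intermittently entrained to coupled neighbours with an imposed nonzero
lag; the estimated PLI of a directly coupled pair approximates the
programmed coupling strength, and the spanning tree of the estimated
matrix recovers the programmed backbone. Cohorts interpolate each
subject's coupling backbone between a chain and a star, and shift the
mixture with sleep deprivation in opposite directions for patients
(toward path-like) and controls (toward star-like).

## Worked example

Simulate a small cohort with a programmed alpha-band shift and run the full
pipeline (this uses shortened recordings; drop the size overrides for
study-scale runs):

```python
from plinet.pipeline import RunConfig, run_pipeline
from plinet.preprocess import BandDefinition
from plinet.simulate import CohortSpec

cfg = RunConfig(output_dir="demo", seed=1, n_epochs=2, epoch_len=1024,
                n_surrogates=20, bands=(BandDefinition("alpha", 8.0, 13.0),))
tables = run_pipeline(cfg, cohort_spec=CohortSpec(
    n_patients=6, n_controls=6, n_epochs=2, n_samples=1024, seed=1))
print(tables["interaction"])
```

which prints (abridged):

```
     cohort  band     measure  statistic   df        p  fdr_significant
        all alpha path_length   4.569178 1x10 0.058274            False
        all alpha  clustering  12.683818 1x10 0.005169             True
        all alpha leaf_number  28.958763 1x10 0.000310             True
        all alpha    diameter  27.433234 1x10 0.000380             True
added_value alpha leaf_number  19.278689  1x8 0.002315             True
```

The leaf-number interaction is strongly significant because the programmed
shift moves the two groups in opposite directions; the underlying group
means make the direction explicit:

```
condition  routine         sd
group
control       10.5  15.000000   # toward a star: more leaves
patient       10.0   5.666667   # toward a path: fewer leaves
```

The same run writes per-recording connectivity matrices, a long-format
measure table, and report tables (paired t per group, interaction on the
full cohort and on the added-value patient subset, relative band power)
under `demo/`. The equivalent shell commands are
`plinet simulate`, `plinet analyze`, `plinet stats` and `plinet all`.

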