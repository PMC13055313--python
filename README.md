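# xppx

Cross-omics identification of EF-P-dependent translational targets in
*Bacillus subtilis*.

Elongation factor P (EF-P) rescues ribosomes that stall while
synthesizing consecutive prolines; the four-residue **XPPX** window (any
residue, Pro, Pro, any residue) marks the stall-prone sites. In an *efp*
deletion strain, proteins whose translation depends on EF-P drop in
abundance even though their mRNA does not — but a proteome-wide census
is confounded by the mutant's massive transcriptional rewiring and by
the compressed dynamic range of iTRAQ quantification. `xppx` implements
the classification used to untangle this: scan the proteome for XPPX
motifs, call differential transcripts and proteins with layer-specific
fold-change cutoffs, and use the **protein-per-mRNA (TE) ratio** to
separate direct translational targets from transcriptionally driven and
secondary changes.

## The classification

For each protein detected in both layers, with mutant/wild-type ratios
$r_\text{prot}$ and $r_\text{rna}$ and TE ratio
$\mathrm{TE} = r_\text{prot} / r_\text{rna}$:

| rule (first match wins) | mode |
|---|---|
| protein down **and** mRNA down | `transcriptional` |
| protein down **and** XPPX **and** mRNA not down | `efp_direct_candidate` |
| protein down, no XPPX, mRNA not down | `secondary` |
| protein up **and** XPPX **and** TE < 0.7 | `translational_attenuation_masked` |
| otherwise | `unclassified` |

Calls use the layers' published cutoffs, strictly: transcripts
$|\log_2 \mathrm{FC}| > 1$; proteins ratio $> 1.5$ (up) or $< 0.7$
(down), the asymmetric band conventional for isobaric-tag data.
Candidates can be cross-referenced against a Ribo-seq stalling atlas
(±1 residue by default), and up/down calls are aggregated into
per-functional-category summary tables with the mixed-precision
percentage rule (integer percent at ≥ 1%, one decimal below).

Because no raw data ships with the package, a seeded simulator generates
paired datasets with the same causal structure — negative-binomial
counts, planted mRNA effects, planted translational attenuation at XPPX
genes, lognormal measurement noise, and power-law ratio compression
(observed = true^c) — together with ground-truth labels, so the whole
pipeline is testable end to end.

## Worked example

```python
from xppx import PipelineConfig, SimConfig, run_pipeline

config = PipelineConfig(
    out_dir="demo_out", seed=7,
    sim=SimConfig(n_genes=2000, frac_translational=0.4, noise_cv=0.05),
)
result = run_pipeline(config)
print(result.funnel.to_dict())
```

prints

```
{'n_detected_rna': 2000, 'n_detected_protein': 2000,
 'n_rna_up': 233, 'n_rna_down': 308,
 'n_protein_up': 251, 'n_protein_down': 349,
 'n_down_with_xppx': 166, 'n_down_mrna_driven': 246,
 'n_efp_direct': 103}
```

Reading the funnel: of 2000 simulated genes, 349 proteins dropped below
the 0.7 cutoff; 166 of those carry an XPPX motif; removing the 246 with
a concurrent mRNA decrease leaves 103 direct EF-P candidates. Scoring
against the simulator's truth labels
(`xppx.evaluate.score_recovery`) gives precision 1.000 and recall 0.585
for this run — every candidate is a planted target, but the default
compression exponent (c = 0.6) pushes many true attenuation ratios above
the 0.7 cutoff and mRNA co-regulation reroutes others into the
`transcriptional` class, which is exactly the behavior the masked class
and the TE ratio exist to mitigate.

The same run from a shell:

```sh
xppx run-all --simulate --seed 7 --out-dir demo_out
```

writes `inventory.tsv` (one row per protein: calls, TE ratio, mode,
stall support), `funnel.json`, category summaries when a mapping is
given, the simulated inputs, and `run.log`. Stage-wise subcommands
(`simulate`, `scan`, `call`, `integrate`, `summarize`) expose each step
on its own; exit codes are 0 (ok), 1 (input error), 2 (config error).

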