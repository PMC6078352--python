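# ubscan

Analysis pipeline for deep mutational scanning (DMS) of ubiquitin under
chemical perturbations — from barcoded competition sequencing counts to
per-variant fitness landscapes, difference maps against a control,
position sensitivity classes, condition clustering, PCA of perturbation
responses, and ensemble interface ΔΔG aggregation. A synthetic data
generator emulates the complete experiment, so every stage is testable
without any sequencing download.

## Who this is for

Groups running pooled growth competitions of barcoded variant
libraries across treatment conditions — in particular the
ubiquitin-in-yeast design: every single amino-acid substitution
(19 amino acids + stop at positions 2–76; Met1 carries no data),
multiple DNA barcodes per variant, several timepoints, duplicate
cultures per chemical treatment dosed to 25% wild-type growth
inhibition.

## The model

During exponential competition each variant's frequency obeys
p_v(t) ∝ p_v(0)·2^((1+f_v)t), so the log2 frequency ratio to wild type
is linear in elapsed generations with slope f_v. Per-variant fitness is
the ordinary least-squares slope of

    log2((c_v,t + ½) / (c_WT,t + ½))  vs  generations t,

rescaled so wild type = 0 and the mean nonsense (stop) variant = −1.
On this scale a position's average substitution fitness classifies it
as tolerant (≥ −0.075), intermediate, or sensitive (≤ −0.35), using the
minimum average across all tested conditions. Condition vectors are
compared by Ward clustering on Euclidean distances (absolute fitness,
complete-case mutants) and by PCA of treatment-minus-control difference
vectors (stops excluded); interface ΔΔG predictions are the ensemble
mean of (E_mut_complex − E_mut_separated) − (E_wt_complex −
E_wt_separated) over conformational models.

## Worked example

Simulate the control (DMSO) and a nickel-stress condition at
sequencing depth 10⁶ with two replicates, estimate both landscapes,
and ask what nickel does to the key poly-ubiquitin linkage mutant
K63R:

```python
from ubscan.synthetic_data import (default_condition_panel, generate_library,
    generate_true_landscape, simulate_competition, CompetitionConfig)
from ubscan.barcode_counts import collapse_to_variants
from ubscan.fitness import (estimate_raw_fitness, normalize_landscape,
    average_replicates)
from ubscan.landscape import (difference_map, position_average,
    min_across_conditions, classify_positions)

cfg = default_condition_panel(seed=1)          # 17-condition study design
truth = generate_true_landscape(cfg)
bmap = generate_library(barcodes_per_variant=2, seed=1)
comp = CompetitionConfig(depth=1_000_000, n_replicates=2, seed=1)

landscapes = {}
for name in ("DMSO", "Nickel"):
    reps = []
    for table in simulate_competition(truth[name], bmap, comp):
        counts = collapse_to_variants(table, bmap)
        raw = estimate_raw_fitness(counts)
        reps.append(normalize_landscape(raw, cfg.wt_sequence, name, table.replicate))
    landscapes[name] = average_replicates(reps)

diff = difference_map(landscapes["Nickel"], landscapes["DMSO"])
print("K63R fitness shift under nickel:", round(diff.values.at[63, "R"], 3))

classes = classify_positions(min_across_conditions(
    [position_average(l) for l in landscapes.values()]))
print("position classes:", classes.labels.value_counts().to_dict())
```

Output:

```
K63R fitness shift under nickel: -0.226
position classes: {'intermediate': 66, 'tolerant': 7, 'sensitive': 2}
```

The −0.23 shift recovers the simulated nickel effect at position 63
(a sensitizing shift of −0.25 blurred by sampling noise); taking the
minimum average fitness over the two conditions classifies each of the
75 mutable positions.

The same stages are available from the shell:

```sh
ubscan simulate --out-dir demo --conditions DMSO,Nickel --seed 1
ubscan identity MQIFVKTLTG... MQIFVKTLTG...   # percent identity utility
ubscan run --manifest manifest.yaml --out-dir results/
```

`ubscan run` consumes a YAML manifest naming each condition's count
tables (or FASTQ files plus a barcode map) and writes landscapes,
difference maps, the position classification, clustering (merge table,
Newick dendrogram, flat clusters at 6 distance units), PCA tables, and
a JSON run report with input digests.

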