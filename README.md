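# contactdiff

Differential residue-contact analysis of molecular-dynamics ensembles.

`contactdiff` compares structural ensembles of the same protein under
different conditions — wild-type vs point mutant, apo vs peptide-bound —
the way Hsp40/J-domain chaperone studies do it: through residue-residue
contact statistics rather than global structural metrics. It was built
for the analysis pattern where disease-associated J-domain mutations
(e.g. the LGMDD1-type substitutions studied in the yeast Hsp40 Sis1)
subtly rewire interdomain contacts between the J-domain, the G/F- and
G/M-rich linkers and the C-terminal client/co-chaperone binding domains,
without unfolding any individual domain.

## What it computes

For each condition (ensemble of frames):

* **Contact probability matrix** `P_ij` — the fraction of frames in
  which residues i and j are in contact, with two contact definitions:
  Cα–Cα distance ≤ 8.0 Å, or minimum heavy-atom distance ≤ 4.5 Å
  (boundaries inclusive).
* **Mean-distance matrix** — the frame-averaged residue-residue
  distance, a continuous contact-persistence proxy.
* **Per-residue contact frequency** — mean contacts formed per frame,
  `f_i = Σ_j P_ij`.
* **Radius of gyration** `Rg = sqrt(Σ m_i |r_i − r_com|² / Σ m_i)` per
  frame, with 50-frame rolling means and histograms.

For each condition pair (A = perturbed, B = reference):

* **Difference map** `ΔP = P_A − P_B`, with a significance mask
  `|ΔP| ≥ 0.2`.
* **Gain/loss calls** — gained if `ΔP > +0.3`, lost if `ΔP < −0.3`
  (strict), each call additionally required to *persist* in more than
  50% of the frames of the condition in which the contact exists.
* **Per-residue Kullback–Leibler divergence** (bits) between the two
  conditions' contact-probability distributions; residues above 0.1
  bits are flagged as structurally differentiating.
* **Domain-wise contact tables** (e.g. J, GF, GM, CTD blocks) and their
  differences; motif-level profiles (e.g. the HPD tripeptide against a
  chosen domain).
* **Protein–peptide interface profiles** — any-heavy-atom 4.5 Å contact
  frequencies per (protein residue, peptide residue) pair, summed
  peptide contact profiles, and contact counts broken down by
  residue-class pairs (aliphatic/aromatic/polar/charged).

A synthetic-trajectory generator plants residue pairs with prescribed
per-frame Bernoulli contact probabilities in an otherwise contact-free
geometry, so every statistic above has a closed-form expected value —
the entire pipeline is testable without simulation data.

## Worked example

```python
from contactdiff import (
    SyntheticSpec, generate_ensemble, contact_matrix, ContactParams,
    difference_map, filter_significant, gain_loss_map, kld_profile,
    contact_series, persistence_filter,
)

spec = SyntheticSpec(
    n_residues=40, n_frames=5000, seed=42,
    planted_pairs=[
        (5, 20, {"WT": 0.2, "MUT": 0.8}),   # contact gained by the mutant
        (7, 22, {"WT": 0.8, "MUT": 0.3}),   # contact lost by the mutant
        (3, 18, {"WT": 0.9, "MUT": 0.9}),   # unchanged
    ],
)
params = ContactParams(mode="CA")            # 8.0 A Calpha cutoff
mats, trajs = {}, {}
for cond in ("WT", "MUT"):
    _, trajs[cond] = generate_ensemble(spec, cond)
    mats[cond] = contact_matrix(trajs[cond], params, condition=cond)

diff = filter_significant(difference_map(mats["MUT"], mats["WT"]))
calls = gain_loss_map(diff)
print("dP(5,20)  =", round(diff.values[4, 19], 3))
print("dP(7,22)  =", round(diff.values[6, 21], 3))
print("gained    =", [(i + 1, j + 1) for i, j in calls.gained_pairs])
print("lost      =", [(i + 1, j + 1) for i, j in calls.lost_pairs])

pairs = calls.gained_pairs + calls.lost_pairs
pers = persistence_filter(
    contact_series(trajs["MUT"], params, pairs),
    contact_series(trajs["WT"], params, pairs),
    calls,
)
print("persistent=", {(i + 1, j + 1): ok for (i, j), ok in pers.passed.items()})

kld = kld_profile(mats["MUT"], mats["WT"])
print("KLD peaks =", (kld.peaks + 1).tolist(),
      "max =", round(kld.values.max(), 3), "bits")
```

prints

```
dP(5,20)  = 0.588
dP(7,22)  = -0.51
gained    = [(5, 20)]
lost      = [(7, 22)]
persistent= {(5, 20): True, (7, 22): True}
KLD peaks = [5, 7, 20, 22] max = 1.147 bits
```

The planted +0.6 gain and −0.5 loss are recovered to within binomial
sampling error of 5000 frames, they are the only pairs called at the
±0.3 thresholds, both calls persist in more than half the frames of the
condition carrying the contact, and the four residues involved are
exactly the KLD peaks above 0.1 bits.

Real data enter the same way: `load_topology(pdb)` +
`load_trajectory(topology, multi_model_pdb_or_xyz)` +
`strip_non_protein(...)` produce the `Trajectory` objects consumed by
every function above.

## Command line

The same pipeline is scriptable from a shell:

```sh
contactdiff simulate --spec spec.yaml --out fixture/
contactdiff run --config config.yaml       # full multi-condition run
contactdiff contacts --topology top.pdb --trajectory wt.pdb --out wt.tsv
contactdiff diff --a mut.tsv --b wt.tsv --out delta.tsv
contactdiff kld  --a mut.tsv --b wt.tsv --out kld.tsv
```

`run` writes, per condition and condition pair: Rg series/histograms,
both contact matrices, difference/filtered/gain-loss/KLD exports, domain
tables and interface profiles — all as labeled TSV with `#` header
comments, each matrix both at full precision and as a `.fixed.tsv`
mirror, plus a JSON run summary.

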