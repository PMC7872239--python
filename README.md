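# rhosurvey

Tools for surveying microbial rhodopsins across metagenomes. Microbial
rhodopsins are retinal-binding membrane photoproteins that let bacteria and
archaea capture light energy without chlorophyll; comparing their abundance
and family composition across environments (oceans, lakes, soils,
hypersaline mats) requires a chain of statistics that this package
implements as a tested, reusable pipeline:

1. **Fragment classification.** Candidate protein fragments from a profile
   search (HMMER-style hit tables) are assigned to a family (rhodopsin,
   RecA, Rad51) by a quantile rule: after discarding hits with bit score
   below 8, a fragment X is accepted iff its score *S* and profile coverage
   *C* both strictly exceed the *c* = 0.04 quantile of the scores and
   coverages of the positive reference fragments that have the length of X
   and whose alignment interval contains X's interval or is contained by it.
2. **Root-clade profiles.** Query fragments placed on a reference rhodopsin
   tree (jplace files) are binned into the *n* = 44 root clades (RCs) — the
   disjoint subtrees closest to the root — and each metagenome becomes a
   proportion vector
   `p_i = Σ_{f∈RC_i} h_f/l_f / Σ_f h_f/l_f`,
   where *h* is the read support of fragment *f* and *l* its length.
   Metagenomes with fewer than 10 placed fragments are excluded. Family
   proportions follow by weighting each RC's reference-leaf family
   composition by `p_i`.
3. **Abundance normalization.** Rhodopsin content per genome equivalent is
   `RHO_abundance = Σ RL_r / Σ RL_e`, the ratio of rhodopsin to recombinase
   (RecA + Rad51) read densities (`RL = reads/length`), under the
   single-copy assumption for recA/rad51.
4. **Consensus clustering.** Metagenomes are grouped by RC profile through a
   recursive procedure: uninformative RCs are eliminated (sparse, constant,
   or fully correlated columns), an exhaustive grid of distance functions
   (euclidean, maximum, manhattan, canberra, minkowski) × aggregation
   methods (Ward D, Ward D2, single, complete, average, McQuitty, median,
   centroid, k-means) × k ∈ [2, 10] is scored by a panel of cluster-validity
   indices (silhouette, Calinski–Harabasz, Davies–Bouldin, Dunn, C-index,
   point-biserial, McClain–Rao), the winner is elected by index majority,
   and the procedure recurses into each sufficiently large group.
5. **Marker utilities.** Annotation count tables are TPM/CPM-normalized,
   biogeochemical processes are profiled as the CPM mass of bundled KO/COG
   marker groups, and alpha diversity is reported as the effective species
   number (antilog of Shannon entropy).

A synthetic-data module generates every input with planted ground truth
(hit mixtures, reference trees, placements, communities, profile matrices),
so the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
from rhosurvey import (ClassifierConfig, classify_batch, select_root_clades,
                       profile_metagenome, family_proportions, rho_abundance)
from rhosurvey.simulate import (HitSimSpec, CommunitySpec, simulate_hits,
                                simulate_community, simulate_tree,
                                simulate_placements)

# 1. classify simulated profile-search hits against a positive reference set
sim = simulate_hits(HitSimSpec(seed=42))
verdicts = classify_batch(sim.hits, sim.positives, ClassifierConfig())
accepted = np.array([v.accepted for v in verdicts])
print(f"accepted {accepted.sum()}/{len(verdicts)} candidate hits "
      f"(true-hit rate {accepted[sim.labels].mean():.2%}, "
      f"false-hit rate {accepted[~sim.labels].mean():.2%})")

# 2. root-clade profile of one metagenome from placements
tree = simulate_tree(48, seed=7)
rcs = select_root_clades(tree, n_rc=8)
rng = np.random.default_rng(3)
target = dict(zip(rcs.rc_ids, rng.dirichlet(np.ones(8))))
placements, reads = simulate_placements(tree, rcs, target,
                                        n_reads=100_000, seed=11)
profile = profile_metagenome(placements, reads, rcs)
err = max(abs(profile.p[rc] - target[rc]) for rc in rcs.rc_ids)
print(f"profile over {profile.n_fragments} fragments, "
      f"sum={sum(profile.p.values()):.6f}, max |p_i - target| = {err:.4f}")
fams = family_proportions(profile, rcs, tree)
top = max(fams, key=fams.get)
print(f"dominant family: {top} ({fams[top]:.2%})")

# 3. rhodopsins per genome, normalized to single-copy recombinases
rho, rec, q = simulate_community(CommunitySpec(rho_carrier_fraction=0.3,
                                               seed=5))
res = rho_abundance(rho, rec)
print(f"rho_abundance = {res.rho_abundance:.3f} (planted fraction {q})")
```

Output:

```
accepted 98/200 candidate hits (true-hit rate 98.00%, false-hit rate 0.00%)
profile over 80 fragments, sum=1.000000, max |p_i - target| = 0.0005
dominant family: unknown (31.15%)
rho_abundance = 0.291 (planted fraction 0.3)
```

The classifier accepts nearly all genuine rhodopsin fragments and none of
the decoys; the placement profile conserves probability mass and recovers
the generating clade proportions to multinomial precision; and the
abundance estimator returns the planted rhodopsins-per-genome fraction.

## Command line

The same stages are available as subcommands of `rhosurvey`:
`classify`, `profile`, `abundance`, `cluster`, `markers`, `diversity`, and
`simulate` (which writes ready-made fixture files). For example:

```bash
rhosurvey simulate placements --seed 11 --out-dir fixtures
rhosurvey profile --tree fixtures/reference.nwk \
    --annotations fixtures/families.tsv \
    --jplace fixtures/placements.jplace --reads fixtures/reads.tsv \
    --n-rc 10 --out-profiles profiles.tsv
```

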