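# formulanet

Network-pharmacology screening and formula-reduction analysis for
multi-herb traditional medicines.

Multi-herb formulae — here the Uyghur-medicine Yimusake formula used
against erectile dysfunction (ED) — act through many compounds hitting
many protein targets at once. When such a formula contains rare or
ethically problematic animal drugs, the practical question is whether
those components can be deleted without losing the formula's
disease-relevant target coverage. `formulanet` implements the full
desk-side pipeline for answering that question:

1. **Herb–disease mining** (`herb_mining`). For document counts
   *N* (corpus), *K* (disease papers), *n* (herb papers), *k* (joint),
   the association score is the hypergeometric upper tail
   P(X ≥ k) = 1 − Σ_{i=0}^{k−1} C(K,i)·C(N−K,n−i)/C(N,n),
   significant when P < 0.01.
2. **ADME screening** (`adme_screen`). Candidate compounds satisfy oral
   bioavailability OB ≥ 30 % and drug-likeness DL ≥ 0.18, where DL is
   the continuous Tanimoto similarity
   T(a,b) = Σaᵢbᵢ / (Σaᵢ² + Σbᵢ² − Σaᵢbᵢ)
   between a compound's descriptor vector and the mean vector of known
   drugs (0.18 is the DrugBank average). Compounds failing the
   thresholds can be rescued through an explicit literature whitelist.
3. **Target consensus** (`target_consensus`). A (compound, target) pair
   is kept when both a random-forest and an SVM prediction score place
   it in the positive list (> 0.5) and clear the stricter cutoffs
   RF > 0.7 and SVM > 0.8.
4. **C-T networks** (`ct_network`). Bipartite compound–target graphs
   with degree statistics and the shared/specific target partition
   across herb groups, exportable as Cytoscape SIF, GraphML or edge TSV.
5. **Formula comparison** (`formula_compare`). The
   *alternative-removing* decision: a removed component set is
   dispensable when the shared targets cover ≥ 90 % of the target union
   and no removed-only target is disease-associated.
6. **Pathway mapping** (`pathway_map`) onto curated disease pathways
   (NO/cGMP, Ras kinase, VEGF for ED) with a tripartite C-T-P export.

Two compound tables ship with the package: the 66 candidate compounds
of the modified seven-herb formula (with OB/DL and herb attributions)
and the 37 compounds of the three animal drugs (Moschus, Ambra Grisea,
Bullwhip). Score matrices and edge lists are not published for the
study system, so the `synthetic_data` module generates score tables and
paired formula networks with planted ground truth; the default scenario
mirrors the study's shape (66 compounds, 139 comparison targets, 4
removed-only targets, none disease-linked).

## Worked example

```python
import formulanet as fn
from formulanet.core_data import default_whitelist

table1 = fn.load_fixture("table1")
result = fn.screen_library(table1, default_whitelist())
print(len(result.strict_pass), len(result.rescued), len(result.retained))
# 56 10 66
print(result.per_herb_counts["Stigma Croci"])
# (6, 8)  -> 6 strict passes, 8 retained after rescues
print(fn.overlap_percentage(67, 132), fn.overlap_percentage(135, 139, 0))
# 50.76 97.0
```

Of the 66 tabulated compounds, 56 clear the strict OB/DL filter and the
10 whitelisted compounds (e.g. brucine, OB 7.6 %, retained for its
documented pharmacology) bring the candidate set back to 66. The two
percentages are the shared-target figures of the hormone sub-network
(67 of 132 targets shared by all four herbs) and of the animal-drug
comparison (135 of 139 targets shared, i.e. 97 %).

The same workflow is available from a shell:

```sh
formulanet screen fixture:table1 --fixture-whitelist
formulanet simulate --seed 1 --out-dir sim
formulanet compare sim/network_a.tsv sim/network_b.tsv sim/annotations.tsv
```

`compare` exits 0 when the removed components are dispensable, 3 when
they are not, 4 when annotations leave the verdict indeterminate.

## The analysis

The numbered scripts under `analysis/` walk the full study workflow and
write their tables under `results/`:

| script | what it does |
| --- | --- |
| `01_mine_herb_associations.py` | ranks herbs by hypergeometric P against the disease corpus |
| `02_screen_compounds.py` | ADME screen of the packaged compound tables |
| `03_predict_targets.py` | consensus filter over a synthetic RF/SVM score table |
| `04_build_networks.py` | vascular / CNS / hormone C-T networks and overlap statistics |
| `05_compare_formulae.py` | alternative-removing comparison and removal verdict |
| `06_map_pathways.py` | pathway counts and the C-T-P tripartite network |

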