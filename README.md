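# orgamri

Non-invasive MRI monitoring and quality assessment of cerebral
organoids: 3-D organoid segmentation, global cysticity classification,
local cyst segmentation and DTI group statistics — with a synthetic
phantom generator so the whole pipeline is testable without scanner
data.

## Who this is for

Labs imaging organoids in culture tubes with high-field T2*-weighted
MRI (80 µm isotropic is the design resolution) who want automated,
reproducible readouts of organoid volume and quality. On that contrast,
free fluid (culture medium, cyst content) is bright while compact
tissue is darker; every stage of the pipeline builds on this.

## What it computes

**Dice score** for all segmentation evaluation:

    Dice = 2·|A ∩ B| / (|A| + |B|)

with A the ground-truth and B the predicted voxel set (1 = perfect).

**Compactness** for global cysticity. Cysts are filled with fluid
similar to the surrounding medium, so a cystic organoid's mean
intensity approaches the medium's:

    compactness = | μ(int_org) − μ(int_medium) |

`int_org` are organoid-voxel intensities from the organoid
segmentation; `int_medium` comes from a 2-D Otsu threshold applied on
every interior organoid-containing coronal plane (bright fluid vs. dark
background) minus organoid voxels, discarding the first and last
organoid-containing planes. Low compactness ⇒ cystic; classification
uses −compactness as the cystic score and is evaluated by ROC AUC.

**Segmentation** is either a deterministic Multi-Otsu baseline (middle
intensity class = tissue, largest connected component) or a compact
3-D U-Net implemented in pure numpy (im2col convolutions + hand-derived
backprop), trained with Adam (lr 10⁻³, weight decay 10⁻⁷), batch size 1
and the composite loss `1·BCE + 10·(1 − softDice)`, evaluated with
organoid-wise leave-one-out cross-validation (all time points of one
organoid form one test set; the rest split 80/20 train/validation).

**Cyst segmentation** reuses the same harness (5000-iteration default
schedule) after excluding samples with fewer than 1000 cyst voxels
(0.512 mm³ at 80 µm, printed as 0.51).

**DTI statistics**: per-sample means of Trace/FA/eigenvalue maps over
the organoid mask, two-sided Welch t-tests between cystic and
non-cystic groups, Holm–Šídák multiplicity correction across the five
maps.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Simulate a 20-phantom cohort (10 cystic / 10 non-cystic), score it with
compactness, and classify:

```python
import numpy as np
from orgamri import (generate_cohort, minmax_normalize, compactness,
                     classify_cysticity)

cohort = generate_cohort(n_organoids=20, days=[30], cystic_fraction=0.5,
                         seed=2024)
results = [(compactness(minmax_normalize(s.volume), s.organoid_mask),
            s.cystic_label) for s in cohort]
roc, calls = classify_cysticity(results)

for (res, label), call in zip(results[:4], calls[:4]):
    print(f"cystic={label!s:5}  compactness={res.compactness:.3f}  "
          f"called cystic={call}")
print(f"ROC AUC = {roc.auc:.2f}")
```

Output:

```
cystic=False  compactness=0.516  called cystic=False
cystic=False  compactness=0.511  called cystic=False
cystic=True   compactness=0.448  called cystic=True
cystic=False  compactness=0.517  called cystic=False
ROC AUC = 1.00
```

Non-cystic phantoms sit around compactness ≈ 0.52 (dark tissue vs.
bright medium after min–max normalization), cystic ones fall toward 0
as the fluid fraction grows, and the two groups separate completely
(AUC 1.0).

The same analyses are available from the shell:

```sh
orgamri simulate --out cohort/ --seed 7
orgamri baseline-otsu --manifest cohort/manifest.csv --out otsu/
orgamri compactness   --manifest cohort/manifest.csv --out comp/
orgamri run           --out full_run/ --seed 7     # all stages, one report
```

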