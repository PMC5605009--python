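# mrsynthct

Bulk-density synthetic CT generation from multi-sequence brain MRI, with a
quantitative image-similarity evaluation suite (overlap coefficients,
histogram distances, gamma-index analysis on CT numbers).

## The problem

MR-only radiotherapy planning needs electron-density information that MRI
does not provide. A practical workaround is *bulk-density assignment*:
segment the main anatomies on MR and replace each one with a single
representative CT number (HU), producing a synthetic "bulk" CT (**B_CT**).
The degenerate baseline is the *water-equivalent* CT (**W_CT**): body
interior 0 HU, exterior −1000 HU, no inhomogeneity correction. This package
implements the full pipeline for the intracranial region and — its real
focus — the methodology for judging how close each synthetic CT comes to a
reference CT, using image similarity rather than dose recalculation.

Eight anatomies are segmented from three MR sequences (T1-weighted,
T2-weighted, and the ultrashort-echo PETRA sequence, on which bone retains
signal): body, air, eyeball, lens, cavity, ventricle, brainstem, bone.
The default bulk HU table assigns −1000, 0, 300, 300, −1000, 15, −50 and
1000 HU respectively.

Because clinical image sets cannot ship with a package, a synthetic
digital head phantom generates co-registered cases (ground-truth labels,
T1/T2/PETRA, reference CT) that emulate a 20-patient cohort at 2.5 mm
slice thickness and 30 cm field of view; every stage is exercised
end-to-end on it.

## The metrics

Segmentation quality, per class, in percent (A = segmentation, G = truth):

    DSC = 200·|A∩G| / (|A|+|G|)       (Dice similarity coefficient)
    FND = 200·|A̅∩G| / (|A|+|G|)       (false-negative Dice: under-segmentation)
    FPD = 200·|A∩G̅| / (|A|+|G|)       (false-positive Dice: over-segmentation)

with the identity FND + FPD = 200 − 2·DSC.

Global similarity between unit-normalised CT-number histograms H₁, H₂
(256 bins over [−1000, 1000] HU by default): Pearson **correlation**
(perfect match 1), symmetric **chi-square** Σ(H₁−H₂)²/(H₁+H₂) (perfect
match 0), **intersection** Σ min(H₁,H₂) (perfect match 1), and the
**Bhattacharyya distance** √(1 − Σ√(H₁H₂)/√(ΣH₁·ΣH₂)) (perfect match 0).

Local similarity via the gamma index evaluated on CT numbers instead of
doses: for each reference voxel r₁ inside the per-slice body bounding
rectangle,

    γ(r₁) = min over r₂ of √( |r₁−r₂|²/Δd_M² + (D₂(r₂)−D₁(r₁))²/ΔD_M² )

with distance-to-agreement Δd_M in mm and value criterion ΔD_M as a
percentage of the reference dynamic range in the ROI. A voxel passes when
γ ≤ 1; pass rates are reported at 3 mm/3 %, 2 mm/2 % and 1 mm/1 %.
Cohort comparisons between W_CT and B_CT use Welch's two-sample t-test,
and a normal-approximation power analysis verifies the cohort size.

## Worked example

```python
from mrsynthct import stats_report

report = stats_report.run_study(n_cases=20)   # full phantom study
print(report.gamma_table.round(2))
```

prints the gamma pass-rate table of the 20-case default-seed phantom study:

```
                3mm/3%  2mm/2%  1mm/1%
ct_vs_wct_mean   74.45   63.06   39.90
ct_vs_wct_sd      0.77    1.69    2.03
ct_vs_bct_mean   96.21   82.88   52.88
ct_vs_bct_sd      0.75    1.77    2.04
improvement      21.77   19.82   12.98
p_value           0.00    0.00    0.00
```

Reading it: the eight-class bulk CT agrees with the reference CT at
96.2 % of ROI voxels under the 3 mm/3 % criterion versus 74.4 % for the
water-equivalent CT — a 21.8-point improvement, significant under Welch's
test (p ≪ 0.001) — and the ordering 3 mm/3 % ≥ 2 mm/2 % ≥ 1 mm/1 % holds
case by case. `report.hist_table` and `report.overlap_table` hold the
histogram-similarity and per-class DSC/FND/FPD tables of the same run.

The same pipeline is scriptable from the shell:

```bash
mrsynthct phantom --n-cases 1 --seed 5 --outdir cases/
mrsynthct segment --t1 cases/case000_t1.nii.gz --t2 cases/case000_t2.nii.gz \
    --petra cases/case000_petra.nii.gz --out cases/labels.nii.gz
mrsynthct synthesize --mode bct --labels cases/labels.nii.gz --out cases/bct.nii.gz
mrsynthct gamma --reference cases/case000_ct.nii.gz --evaluated cases/bct.nii.gz \
    --body cases/labels.nii.gz --dta 3 --dd 3
```

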