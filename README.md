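# fenplan

Automated fenestration placement planning for physician-modified
endovascular stent-grafts (PMEGs).

## The problem

Complex abdominal aortic aneurysms often involve the visceral segment, so a
stent-graft must carry **fenestrations** — holes cut in the fabric — that
line up with the ostia of the celiac artery (CA), superior mesenteric
artery (SMA) and the renal arteries (RRA/LRA) to preserve their flow.  When
a custom-manufactured device is unavailable, surgeons cauterize
fenestrations into an off-the-shelf endograft before implantation.  The
hard part is finding a rotational and axial orientation of the graft in
which every fenestration avoids the metal zigzag strut rings (metal cannot
be cauterized) while staying as close as possible to each vessel's true
position.  Done by hand this is slow, error-prone trial and error.

`fenplan` automates the search.  Each fenestration target is reduced to two
surface coordinates on the deployed graft:

* **AL** (arclength) — circumferential distance around the graft,
  `AL = (phi / 360) * pi * D`, with `phi` measured clockwise (viewed from
  proximal) from an anterior datum vector;
* **PGD** (proximal graft distance) — axial distance from the graft's
  proximal fabric edge.

The graft is unrolled into a binary **graft mask** (strut material = 1) and
the vessel constellation into a **fenestration mask** (discs of the vessel
diameters).  Sliding the fenestration mask over the graft mask in AL
(rotation, periodic) and PGD (translation) is a 2D cross-correlation; valid
alignments are offsets with zero overlap.  Among them the planner picks the
one minimizing the summed deviation

```
delta = sqrt(dAL^2 + dPGD^2)        (per vessel, mm)
```

from the measured ostium positions.  If no rigid alignment exists, the
renal fenestrations (non-prioritized vessels) may independently shift up to
3 mm posteriorly in AL — a displacement experienced operators tolerate for
renal cannulation — while CA/SMA stay rigid.

The chosen 2D design is then rendered in 3D: a cylindrical graft mesh is
lofted along the aortic centerline spline, flattened onto a rectangle with
a cotangent-weight Laplacian harmonic map (`L = D − W`,
`w_ij = (cot a_ij + cot b_ij)/2`, boundary pinned to the rectangle), and
the design is carried back to the surface through barycentric coordinates
(`lambda = T^-1 (p − r3)`), yielding operating-room instructions and a
textured 3D overlay.

## Worked example

```python
import fenplan as fp

# synthetic CT-like case with known ground truth: straight aorta,
# four visceral ostia, 0.25 mm measurement noise
case = fp.generate_case("straight", 0.25, seed=7)

model = fp.FenestrationPlanner.from_synthetic(case)
plan = model.fit()
print(plan.summary())
```

```
Fenestration plan
================================================================
template:           thoracic-straight-26
deployed diameter:  24.1 mm (circumference 75.8 mm)
valid fit:          True
global offsets:     dAL = +0.00 mm, dPGD = +0.00 mm
offsets examined:   88476 (20572 valid)
----------------------------------------------------------------
vessel  AL_mm  PGD_mm  diameter_mm  delta_f_mm  relaxation_mm note
    CA  74.81   22.07          7.0         0.0            0.0
   SMA   3.55   28.97          7.0         0.0            0.0
   RRA  54.69   53.48          6.0         0.0            0.0
   LRA  20.96   58.51          6.0         0.0            0.0
```

The deployed diameter (24.1 mm) is the mean lumen diameter over the
proximal landing zone (first 10% of graft length), capped at the fabric's
nominal 26 mm.  `AL_mm`/`PGD_mm` are the cautery positions on the unrolled
graft; `delta_f_mm` is each fenestration's deviation from its measured
ostium — zero here because the measured constellation itself admits a
strut-free fit, so no global offset is needed.  `plan.save_instructions(out)`
writes the instruction diagram (PNG), the CSV table, a JSON report, and the
textured OBJ mesh for 3D review.

The same pipeline runs from files (NIfTI lumen labelmap + ostia CSV):

```
fenplan plan --config plan.yaml --out plan_out
fenplan flatten --template thoracic-straight-26 --out mask.png
fenplan simulate --profile tortuous --seed 3 --noise 0.5 --out case_dir
```

Exit codes: 0 valid plan, 2 no strut-free fit, 1 input error.

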