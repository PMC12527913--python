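#!/usr/bin/env python
"""Focal-adhesion orientation and ER association at the two edge types.

Convex-like scene: perpendicular FAs seeded on ER tubules; concave-like
scene: parallel FAs seeded on sheets.  Detects punctae, builds the 6-bin
0-90 deg Fourier orientation histogram of the FA channel, classifies
angles (0-18 parallel / 72-90 perpendicular) and tabulates ER contact.
Writes results/fa_orientation.csv and results/fa_association.csv.
"""

import os
import sys
from dataclasses import replace

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from ermorph.orientation import detect_fa, directionality_fourier, fa_er_association
from ermorph.segmentation import ClassMask
from ermorph.synth import SynthSpec, render_er, render_fa

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    hist_rows, assoc_rows = [], []
    cases = {
        "convex": dict(kappa=0.05, f_true=0.7, fa_mean_angle=85.0, on="tubule"),
        "concave": dict(kappa=-0.05, f_true=0.3, fa_mean_angle=8.0, on="sheet"),
    }
    for name, c in cases.items():
        er_spec = SynthSpec(seed=800, kappa=c["kappa"], f_true=c["f_true"],
                            front_depth=5.0)
        _, gt = render_er(er_spec)
        fa_spec = replace(er_spec, fa_mean_angle=c["fa_mean_angle"],
                          fa_concentration=40.0, fa_count=25)
        on_mask = gt.mask == (1 if c["on"] == "tubule" else 2)
        fa_img, _ = render_fa(fa_spec, on_mask=on_mask)
        hist = directionality_fourier(fa_img, n_bins=6, angle_range=(0, 90))
        for lo, hi, w in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.weights):
            hist_rows.append(dict(edge=name, bin_lo_deg=lo, bin_hi_deg=hi,
                                  weight=round(float(w), 4)))
        fas = detect_fa(fa_img, min_area_um2=0.05)
        ermask = ClassMask(labels=gt.mask, pixel_size=er_spec.pixel_size)
        table = fa_er_association(fas, ermask, contact_radius_um=0.3)
        for cls, stats in table.items():
            assoc_rows.append(dict(edge=name, fa_class=cls, **{
                k: round(v, 3) for k, v in stats.items()}))
    pd.DataFrame(hist_rows).to_csv(os.path.join(OUT, "fa_orientation.csv"),
                                   index=False)
    df = pd.DataFrame(assoc_rows)
    df.to_csv(os.path.join(OUT, "fa_association.csv"), index=False)
    print(df.to_string(index=False))
    print("\nPerpendicular adhesions sit on tubules at the convex-like edge; "
          "parallel adhesions on sheets at the concave-like edge.")


if __name__ == "__main__":
    main()
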