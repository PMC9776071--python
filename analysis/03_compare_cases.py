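#!/usr/bin/env python
"""Cross-case comparison of the three phantom reports.

Loads the per-case JSON reports produced by 02_run_cases.py, builds the
pairwise fold-ratio / percent-difference table, and draws violin plots of
the surrogate TAWSS distribution over the apex-anchored 17 mm ICA region
of interest for each case.
"""
import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from plaquestruct.hemodynamics import ROISpec, roi_stats, surrogate_wss_field, tawss
from plaquestruct.phantom import PhantomConfig, make_bifurcation_geometry, make_flow_waveform
from plaquestruct.wallstress import compare_patients

STENOSES = (0.81, 0.83, 0.82)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cases", type=Path, default=Path("results/cases"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    reports = []
    for i in range(3):
        path = args.cases / f"case{i + 1}_report.json"
        if not path.exists():
            raise SystemExit(f"{path} missing; run analysis/02_run_cases.py first")
        reports.append(json.loads(path.read_text()))

    table = compare_patients(reports, case_ids=[r["case_id"] for r in reports])
    table.to_csv(args.outdir / "case_comparisons.csv", index=False)
    print(table.to_string(index=False))

    # TAWSS ROI distributions (surrogate) per case
    fig, ax = plt.subplots(figsize=(6, 4))
    data = []
    for f in STENOSES:
        geom = make_bifurcation_geometry(PhantomConfig(stenosis_fraction=f))
        flow = make_flow_waveform(1.0, 6.0, 18.0)
        m = tawss(surrogate_wss_field(geom, flow))
        data.append(roi_stats(m, ROISpec("ICA", 0.0, 17.0)).values)
    ax.violinplot(data, showmeans=True, showmedians=True)
    ax.set_xticks([1, 2, 3], [f"case{i+1}\n({int(100*f)}%)" for i, f in enumerate(STENOSES)])
    ax.set_ylabel("TAWSS over 17 mm ICA ROI (Pa, surrogate)")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(args.outdir / "figures_tawss_roi_violin.png", dpi=150)
    print(f"wrote {args.outdir}/case_comparisons.csv and TAWSS violin figure")


if __name__ == "__main__":
    main()
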