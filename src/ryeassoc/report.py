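"""Human-readable markdown report over a run's artifact directory.

Sections mirror the standard presentation of this kind of study:
per-platform phenotype distribution summaries, allelic-effect
distributions split by significance, effect-size (percent genetic
variance explained) histograms, a haplotype table (P, effect, percent
genetic variation explained) and the significant-overlap counts.
Missing artifacts skip their section with a notice.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ryeassoc import io as rio
from ryeassoc.types import PLATFORMS


def _boxplot_stats(values: pd.Series) -> dict:
    v = values.dropna()
    if v.empty:
        return {}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"min": float(v.min()), "q1": float(q1), "median": float(med),
            "q3": float(q3), "max": float(v.max()), "n": int(len(v))}


def _hist_line(values: pd.Series, edges: np.ndarray) -> str:
    counts, _ = np.histogram(values.dropna(), bins=edges)
    cells = " | ".join(str(c) for c in counts)
    labels = " | ".join(f"{edges[i]:g}-{edges[i+1]:g}"
                        for i in range(len(edges) - 1))
    return f"| {labels} |\n|{'---|' * (len(edges) - 1)}\n| {cells} |\n"


def render_report(artifact_dir, out_path, alpha: float = 0.05) -> Path:
    """Render the markdown report; returns the output path."""
    d = Path(artifact_dir)
    lines = ["# ryeassoc run report", ""]

    # phenotype distributions -------------------------------------------
    lines.append("## Phenotype distributions (per-genotype means)")
    phen_path = d / "phenotypes.tsv"
    if phen_path.exists():
        phen = rio.read_phenotype_table(phen_path)
        for plat in PLATFORMS:
            rows = phen.platform(plat)
            if rows.empty:
                continue
            means = rows.groupby("genotype_id")["value"].mean()
            st = _boxplot_stats(means)
            lines.append(f"- **{plat}**: median {st['median']:.2f}, "
                         f"IQR [{st['q1']:.2f}, {st['q3']:.2f}], "
                         f"range [{st['min']:.2f}, {st['max']:.2f}] "
                         f"over {st['n']} genotypes")
    else:
        lines.append("*(phenotypes.tsv missing — section skipped)*")
    lines.append("")

    # allelic effects and effect sizes ----------------------------------
    lines.append(f"## Marker scan (significance at P < {alpha:g})")
    any_scan = False
    for plat in PLATFORMS:
        p = d / f"scan_{plat}.tsv"
        if not p.exists():
            continue
        any_scan = True
        res = rio.read_results(p).dropna(subset=["p"])
        sig = res[res["p"] < alpha]
        lines.append(f"### {plat}")
        lines.append(f"- {len(sig)} of {len(res)} sites significant; "
                     f"allelic effects range "
                     f"[{res['beta'].min():.2f}, {res['beta'].max():.2f}]"
                     + (f"; significant effects "
                        f"[{sig['beta'].min():.2f}, {sig['beta'].max():.2f}]"
                        if len(sig) else ""))
        ve = res["var_explained_pct"].dropna()
        if len(ve):
            lines.append(f"- % genetic variance explained: median "
                         f"{ve.median():.2f}, max {ve.max():.2f}")
            edges = np.array([0, 1, 2, 5, 10, 20, 50, 100], dtype=float)
            lines.append("")
            lines.append(_hist_line(ve, edges))
    if not any_scan:
        lines.append("*(no scan results — section skipped)*")
    lines.append("")

    # haplotype table -----------------------------------------------------
    lines.append("## Haplotype associations")
    hap_frames = {plat: rio.read_results(d / f"haplo_{plat}.tsv")
                  for plat in PLATFORMS if (d / f"haplo_{plat}.tsv").exists()}
    if hap_frames:
        lines.append("| Gene | Haplotype | Platform | P-value | beta_Hap | "
                     "% genetic variation explained |")
        lines.append("|---|---|---|---|---|---|")
        for plat, df in hap_frames.items():
            for _, r in df.iterrows():
                if pd.isna(r["p"]):
                    continue
                name = ("Overall" if r["kind"] == "haplotype_overall"
                        else str(r["unit"]).split(":", 1)[1])
                beta = "-" if pd.isna(r["beta"]) else f"{r['beta']:.3f}"
                ve = ("-" if pd.isna(r["var_explained_pct"])
                      else f"{r['var_explained_pct']:.1f}")
                lines.append(f"| {r['gene']} | {name} | {plat} | "
                             f"{r['p']:.3g} | {beta} | {ve} |")
    else:
        lines.append("*(no haplotype results — section skipped)*")
    lines.append("")

    # epistasis and overlaps ---------------------------------------------
    lines.append("## Gene x gene interactions")
    n_pairs = []
    for plat in PLATFORMS:
        p = d / f"epistasis_{plat}.tsv"
        if p.exists():
            df = rio.read_results(p).dropna(subset=["p"])
            n_pairs.append(f"{plat}: {(df['p'] < alpha).sum()} of {len(df)} "
                           "pairs significant")
    lines.append("; ".join(n_pairs) if n_pairs
                 else "*(no epistasis results — section skipped)*")
    lines.append("")

    lines.append("## Cross-platform concordance and overlap")
    xp = d / "xplatform.tsv"
    if xp.exists():
        df = rio.read_results(xp)
        for _, r in df.iterrows():
            lines.append(f"- r({r['platform_a']}, {r['platform_b']}) = "
                         f"{r['r']:.2f} over {int(r['n_units'])} units "
                         f"({r['subset']})")
    sj = d / "summary.json"
    if sj.exists():
        with open(sj) as fh:
            summary = json.load(fh)
        oc = summary.get("overlap_counts", {})
        lines.append(f"- significant in >=1 platform: {oc.get('>=1', 0)}; "
                     f">=2: {oc.get('>=2', 0)}; all: {oc.get('all', 0)}")
    lines.append("")

    out_path = Path(out_path)
    out_path.write_text("\n".join(lines), encoding="utf-8")
    return out_path
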