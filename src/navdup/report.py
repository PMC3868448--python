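"""Human-readable table renderers for the CLI reports.

Each report has a machine-readable full-precision CSV twin; the renderers
here produce the display form, with "observed (expected)" cells at three
decimals and test statistics at their conventional printed precision.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .clone_typing import SpecimenHaplotypeProfile, profiles_frame
from .copy_number import QpcrSummary
from .cross_analysis import SITE1011_CATEGORIES, CrossVerdict
from .hwe_analysis import CANONICAL_CATEGORIES, HweResult
from .locus_model import category_column


def render_markdown(df: pd.DataFrame) -> str:
    """Minimal GitHub-style markdown table (no external dependency)."""
    headers = [str(c) for c in df.columns]
    rows = [["" if pd.isna(v) else str(v) for v in row] for row in df.itertuples(index=False)]
    widths = [
        max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
        for i, h in enumerate(headers)
    ]
    def line(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    out = [line(headers), "| " + " | ".join("-" * w for w in widths) + " |"]
    out.extend(line(r) for r in rows)
    return "\n".join(out) + "\n"


def hwe_display_frame(results: Sequence[HweResult]) -> pd.DataFrame:
    """One row per sample: 'obs (exp)' cells plus the 'chi2, df, p' column."""
    rows = []
    for r in results:
        row = {
            "locality": r.sample.locality,
            "status": r.sample.status,
            "n": r.sample.n,
        }
        for key in CANONICAL_CATEGORIES:
            col = category_column(key)
            if key in r.sample.counts:
                obs = r.sample.counts[key] / r.sample.n
                row[col] = f"{obs:.3f} ({r.expected[key]:.3f})"
            else:
                row[col] = "-"
        chi2 = "inf" if np.isinf(r.chi2) else f"{r.chi2:.1f}"
        row["chi2, df, p"] = f"{chi2}, {r.df}, {r.p:.4f}"
        rows.append(row)
    return pd.DataFrame(rows)


def cross_display_frame(verdicts: Sequence[CrossVerdict]) -> pd.DataFrame:
    """One row per cross: observed counts, then per-hypothesis expected / code."""
    rows = []
    for v in verdicts:
        row = {
            "cross": v.cross_id,
            "generation": v.generation,
            "observed (Ile/Ile, Ile/Met)": f"{v.observed.get('Ile/Ile', 0)}, {v.observed.get('Ile/Met', 0)}",
        }
        for t in v.tests:
            expected = ", ".join(
                str(t.expected_int[c]) for c in SITE1011_CATEGORIES[:2]
            )
            row[t.label] = f"{expected} [{t.code}, p={t.p:.3g}]"
        row["not rejected"] = ";".join(v.not_rejected) or "none"
        rows.append(row)
    return pd.DataFrame(rows)


def cnv_display_frame(summary: QpcrSummary) -> pd.DataFrame:
    """Copy-number table: per-assay mean dCT (SD) and ddCT, then summary and cn."""
    lineages = list(summary.lineages)
    assays = sorted({a.assay for s in summary.lineages.values() for a in s.assays}, key=str)
    rows = []
    for assay in assays:
        row = {"assay": str(assay)}
        for lineage in lineages:
            match = [a for a in summary.lineages[lineage].assays if a.assay == assay]
            if match:
                a = match[0]
                row[lineage] = f"{a.mu_dct:.1f} ({a.sd_dct:.2f}) ddCT={a.ddct:.1f}"
            else:
                row[lineage] = "-"
        rows.append(row)
    mu_row = {"assay": "mean ddCT (SD)"}
    cn_row = {"assay": "cn"}
    for lineage in lineages:
        s = summary.lineages[lineage]
        mu_row[lineage] = f"{s.mu_ddct:.1f} ({s.sd_ddct:.2f})"
        cn_row[lineage] = str(s.cn)
    rows.extend([mu_row, cn_row])
    return pd.DataFrame(rows)


def clones_display_frame(profiles: Sequence[SpecimenHaplotypeProfile]) -> pd.DataFrame:
    return profiles_frame(profiles)
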