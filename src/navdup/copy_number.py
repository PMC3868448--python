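"""TaqMan relative copy-number arithmetic (comparative-CT method).

Per replicate, the target gene's CT is normalised by the single-copy
reference gene (``delta_ct``); per lineage and assay, replicate delta-CTs are
averaged; each test lineage is then referenced to the calibrator lineage
(``delta_delta_ct``) and converted to a diploid copy number.

Sign convention: with ``ddCT = mean_dCT(test) - mean_dCT(reference)``, a
lineage with extra copies amplifies earlier, so its ddCT is *negative* and
the copy number is ``cn_ref * 2**(-mean_ddCT)``.  Amplification efficiency is
taken as 100% (one cycle = a factor of two).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._util import round_half_away

GENE_ROLES = ("target", "reference")


@dataclass(frozen=True)
class QpcrMeasurement:
    """One well: a CT value for one gene role of one replicate."""

    lineage: str
    assay: Union[int, str]
    pool: Union[int, str]
    replicate: Union[int, str]
    gene: str  # "target" or "reference"
    ct: float

    def __post_init__(self) -> None:
        if self.gene not in GENE_ROLES:
            raise ValueError(f"gene role must be one of {GENE_ROLES}: {self.gene!r}")
        if self.ct <= 0:
            raise ValueError("ct must be positive")


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """Target CT normalised by the reference gene: ``ct_target - ct_reference``."""
    return ct_target - ct_reference


def delta_delta_ct(mu_dct_test: float, mu_dct_reference: float) -> float:
    """Test lineage referenced to the calibrator: ``mu_dct_test - mu_dct_reference``."""
    return mu_dct_test - mu_dct_reference


def copy_number(mu_ddct: float, cn_ref: int = 2) -> Tuple[float, int]:
    """Diploid copy number from the averaged ddCT.

    Returns ``(cn_real, cn_integer)`` with ``cn_real = cn_ref * 2**(-mu_ddct)``
    and the integer rounded half away from zero.
    """
    if cn_ref < 1:
        raise ValueError("cn_ref must be >= 1")
    cn_real = cn_ref * 2.0 ** (-mu_ddct)
    return cn_real, round_half_away(cn_real)


@dataclass
class AssaySummary:
    """Per (lineage, assay): replicate mean and SD of delta-CT, and the ddCT."""

    assay: Union[int, str]
    mu_dct: float
    sd_dct: float
    ddct: Optional[float] = None


@dataclass
class LineageSummary:
    """Per lineage: assay summaries, averaged ddCT and the copy-number estimate."""

    lineage: str
    assays: List[AssaySummary]
    mu_ddct: float
    sd_ddct: float
    cn_real: float
    cn: int


@dataclass
class QpcrSummary:
    """Whole-plate summary, shaped like the published copy-number table."""

    reference_lineage: str
    lineages: Dict[str, LineageSummary]

    def __getitem__(self, lineage: str) -> LineageSummary:
        return self.lineages[lineage]


def replicate_delta_cts(
    measurements: Sequence[QpcrMeasurement],
) -> Dict[Tuple[str, Union[int, str]], List[float]]:
    """Pair target/reference wells per replicate; (lineage, assay) -> delta-CTs."""
    cts: Dict[tuple, Dict[str, float]] = {}
    for m in measurements:
        key = (m.lineage, m.assay, m.pool, m.replicate)
        slot = cts.setdefault(key, {})
        if m.gene in slot:
            raise ValueError(f"duplicate {m.gene} measurement for {key}")
        slot[m.gene] = m.ct
    out: Dict[Tuple[str, Union[int, str]], List[float]] = {}
    for (lineage, assay, pool, replicate), roles in sorted(
        cts.items(), key=lambda kv: tuple(map(str, kv[0]))
    ):
        missing = [r for r in GENE_ROLES if r not in roles]
        if missing:
            raise ValueError(
                f"replicate {(lineage, assay, pool, replicate)} missing {missing}"
            )
        out.setdefault((lineage, assay), []).append(
            delta_ct(roles["target"], roles["reference"])
        )
    return out


def _summarize(
    mu_dct: Mapping[str, Mapping[Union[int, str], float]],
    sd_dct: Mapping[str, Mapping[Union[int, str], float]],
    reference_lineage: str,
    cn_ref: int,
) -> QpcrSummary:
    if reference_lineage not in mu_dct:
        raise ValueError(f"reference lineage {reference_lineage!r} absent from data")
    ref = mu_dct[reference_lineage]
    lineages: Dict[str, LineageSummary] = {}
    for lineage, per_assay in mu_dct.items():
        assays = []
        ddcts = []
        for assay, mu in per_assay.items():
            if assay not in ref:
                raise ValueError(
                    f"assay {assay!r} of lineage {lineage!r} has no reference-lineage match"
                )
            ddct = delta_delta_ct(mu, ref[assay])
            assays.append(
                AssaySummary(assay=assay, mu_dct=mu, sd_dct=sd_dct[lineage][assay], ddct=ddct)
            )
            ddcts.append(ddct)
        mu_ddct = float(np.mean(ddcts))
        sd_ddct = float(np.std(ddcts, ddof=1)) if len(ddcts) > 1 else 0.0
        cn_real, cn = copy_number(mu_ddct, cn_ref=cn_ref)
        lineages[lineage] = LineageSummary(
            lineage=lineage,
            assays=assays,
            mu_ddct=mu_ddct,
            sd_ddct=sd_ddct,
            cn_real=cn_real,
            cn=cn,
        )
    return QpcrSummary(reference_lineage=reference_lineage, lineages=lineages)


def analyze_plate(
    measurements: Sequence[QpcrMeasurement],
    reference_lineage: str,
    cn_ref: int = 2,
) -> QpcrSummary:
    """Full pipeline from raw CT wells to per-lineage copy numbers."""
    if not measurements:
        raise ValueError("no measurements")
    dcts = replicate_delta_cts(measurements)
    mu: Dict[str, Dict[Union[int, str], float]] = {}
    sd: Dict[str, Dict[Union[int, str], float]] = {}
    for (lineage, assay), values in dcts.items():
        mu.setdefault(lineage, {})[assay] = float(np.mean(values))
        sd.setdefault(lineage, {})[assay] = (
            float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        )
    return _summarize(mu, sd, reference_lineage, cn_ref)


def summarize_from_means(
    mu_dct: Mapping[str, Sequence[float]],
    reference_lineage: str,
    cn_ref: int = 2,
) -> QpcrSummary:
    """Summary from already-averaged per-assay delta-CTs (one value per assay)."""
    mu = {lin: {i + 1: float(v) for i, v in enumerate(vals)} for lin, vals in mu_dct.items()}
    sd = {lin: {a: 0.0 for a in per} for lin, per in mu.items()}
    return _summarize(mu, sd, reference_lineage, cn_ref)


def read_qpcr_csv(path) -> List[QpcrMeasurement]:
    """Read CT wells: ``lineage,assay,pool,replicate,gene,ct``."""
    df = pd.read_csv(path)
    required = ["lineage", "assay", "pool", "replicate", "gene", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    return [
        QpcrMeasurement(
            lineage=str(row.lineage),
            assay=row.assay,
            pool=row.pool,
            replicate=row.replicate,
            gene=str(row.gene),
            ct=float(row.ct),
        )
        for row in df.itertuples()
    ]


def summary_frame(summary: QpcrSummary) -> pd.DataFrame:
    """Tidy frame: one row per lineage x assay plus a per-lineage summary row."""
    rows = []
    for lineage, s in summary.lineages.items():
        for a in s.assays:
            rows.append(
                {
                    "lineage": lineage,
                    "assay": a.assay,
                    "mu_dct": a.mu_dct,
                    "sd_dct": a.sd_dct,
                    "ddct": a.ddct,
                    "mu_ddct": np.nan,
                    "sd_ddct": np.nan,
                    "cn_real": np.nan,
                    "cn": np.nan,
                }
            )
        rows.append(
            {
                "lineage": lineage,
                "assay": "all",
                "mu_dct": np.nan,
                "sd_dct": np.nan,
                "ddct": np.nan,
                "mu_ddct": s.mu_ddct,
                "sd_ddct": s.sd_ddct,
                "cn_real": s.cn_real,
                "cn": s.cn,
            }
        )
    return pd.DataFrame(rows)
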