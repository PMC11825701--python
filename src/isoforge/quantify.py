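"""Isoform-resolution abundance, diversity, and depth-saturation metrics.

* per-gene, per-sample transcript proportions and the "abundant" flag
  (present in at least one sample at >= 40% of its gene's reads);
* per-gene isoform diversity (isoform count, novel count, novel ratio);
* saturation analysis: binomial read thinning at a ladder of depth
  fractions, detection at a minimum read support, and a saturating-
  exponential fit ``N(f) = Nmax * (1 - exp(-lam * f))`` whose 95% point
  estimates the saturation depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .model import ConfigError, IsoforgeError


@dataclass(frozen=True)
class AbundanceConfig:
    abundant_threshold: float = 0.40

    def __post_init__(self) -> None:
        if not (0 < self.abundant_threshold <= 1):
            raise ConfigError("abundant_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class SaturationConfig:
    fractions: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
    replicates: int = 20
    min_support: int = 3
    seed: int = 0
    model: str = "exponential"  # or "michaelis_menten"

    def __post_init__(self) -> None:
        if any(not (0 < f <= 1) for f in self.fractions):
            raise ConfigError("fractions must lie in (0, 1]")
        if list(self.fractions) != sorted(self.fractions):
            raise ConfigError("fractions must be sorted ascending")
        if self.model not in ("exponential", "michaelis_menten"):
            raise ConfigError(f"unknown saturation model {self.model!r}")


@dataclass
class GeneDiversity:
    gene_id: str
    n_isoforms: int
    n_novel: int
    novel_ratio: float
    expression: float


@dataclass
class SaturationResult:
    table: pd.DataFrame  # fraction, replicate-mean detected count (per class)
    nmax: Optional[float]
    rate: Optional[float]
    saturation_fraction: Optional[float]
    fit_ok: bool
    message: str = ""
    by_class: dict = field(default_factory=dict)


def isoform_proportions(
    counts: pd.DataFrame, tx2gene: Mapping[str, str]
) -> pd.DataFrame:
    """Per-sample within-gene transcript fractions.

    ``counts`` is transcripts x samples (nonnegative). Fractions within each
    gene and sample sum to 1; gene-sample cells with zero total are NaN
    (flagged, excluded from downstream filters).
    """
    if (counts.to_numpy() < 0).any():
        raise ConfigError("counts must be nonnegative")
    missing = [t for t in counts.index if t not in tx2gene]
    if missing:
        raise IsoforgeError(
            f"transcripts without gene assignment: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    genes = pd.Series({t: tx2gene[t] for t in counts.index}, name="gene")
    totals = counts.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = counts / totals
    return fractions.where(totals > 0)


def abundant_flags(
    proportions: pd.DataFrame, cfg: AbundanceConfig = AbundanceConfig()
) -> pd.Series:
    """True for transcripts reaching the threshold proportion in >=1 sample."""
    return proportions.max(axis=1, skipna=True).fillna(0) >= cfg.abundant_threshold


def gene_diversity(
    calls, expression: Optional[Mapping[str, float]] = None
) -> pd.DataFrame:
    """Per-gene isoform counts and novel-isoform ratio.

    ``calls`` is a sequence of structural calls carrying ``assigned_gene``
    and ``novelty``; ``expression`` optionally maps transcript_id to an
    expression value summed per gene.
    """
    rows = []
    for c in calls:
        if c.assigned_gene is None:
            continue
        rows.append(
            {
                "gene_id": c.assigned_gene,
                "novel": c.novelty == "novel",
                "expr": expression.get(c.transcript_id, 0.0) if expression else 0.0,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "n_isoforms", "n_novel", "novel_ratio", "expression"]
        )
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby("gene_id", sort=True)
        .agg(n_isoforms=("novel", "size"), n_novel=("novel", "sum"), expression=("expr", "sum"))
        .reset_index()
    )
    out["novel_ratio"] = out["n_novel"] / out["n_isoforms"]
    return out[["gene_id", "n_isoforms", "n_novel", "novel_ratio", "expression"]]


def _fit_saturation(fractions: np.ndarray, means: np.ndarray, model: str):
    if model == "exponential":
        def f(x, nmax, lam):
            return nmax * (1.0 - np.exp(-lam * x))
    else:  # michaelis_menten
        def f(x, nmax, k):
            return nmax * x / (k + x)

    p0 = (max(means.max(), 1.0), 2.0)
    with warnings.catch_warnings():
        # a flat (fully saturated) curve has a degenerate covariance; the
        # point estimate is still what we need
        warnings.simplefilter("ignore", OptimizeWarning)
        params, _ = curve_fit(f, fractions, means, p0=p0, maxfev=20000)
    return f, params


def saturation_curve(
    read_counts: Mapping[str, int],
    cfg: SaturationConfig = SaturationConfig(),
    novelty: Optional[Mapping[str, str]] = None,
) -> SaturationResult:
    """Subsample reads per transcript and fit the detection curve.

    ``read_counts`` maps transcript_id -> assigned read count. For each
    depth fraction ``f`` and replicate, each transcript's reads are thinned
    with Binomial(count, f); a transcript is detected when >= ``min_support``
    reads survive. The saturation fraction is the smallest depth at which the
    fitted curve reaches 95% of its asymptote.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = list(read_counts.keys())
    counts = np.array([read_counts[t] for t in ids], dtype=np.int64)
    classes = (
        np.array([novelty.get(t, "known") for t in ids]) if novelty else None
    )
    rows = []
    for f in cfg.fractions:
        for rep in range(cfg.replicates):
            thinned = (
                counts if f >= 1.0 else rng.binomial(counts, f)
            )
            detected = thinned >= cfg.min_support
            row = {"fraction": f, "replicate": rep, "detected": int(detected.sum())}
            if classes is not None:
                for cls in np.unique(classes):
                    row[f"detected_{cls}"] = int(detected[classes == cls].sum())
            rows.append(row)
    table = pd.DataFrame(rows)
    means = table.groupby("fraction")["detected"].mean()
    fr = means.index.to_numpy(dtype=float)
    mu = means.to_numpy(dtype=float)
    result = SaturationResult(
        table=table, nmax=None, rate=None, saturation_fraction=None, fit_ok=False
    )
    try:
        f_model, params = _fit_saturation(fr, mu, cfg.model)
        nmax, rate = float(params[0]), float(params[1])
        if cfg.model == "exponential":
            sat = float(np.log(20.0) / rate) if rate > 0 else None
        else:
            sat = float(19.0 * rate) if rate > 0 else None  # x with f(x)=0.95 Nmax
        result.nmax, result.rate, result.fit_ok = nmax, rate, True
        result.saturation_fraction = sat
    except (RuntimeError, ValueError) as exc:
        result.message = f"fit failed: {exc}"
    if classes is not None:
        for cls in np.unique(classes):
            col = f"detected_{cls}"
            cls_means = table.groupby("fraction")[col].mean()
            try:
                _, p = _fit_saturation(
                    cls_means.index.to_numpy(dtype=float),
                    cls_means.to_numpy(dtype=float),
                    cfg.model,
                )
                result.by_class[cls] = {"nmax": float(p[0]), "rate": float(p[1])}
            except (RuntimeError, ValueError):
                result.by_class[cls] = {"nmax": None, "rate": None}
    return result
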