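"""Probe-level statistics on the fraction data matrix.

The fraction data matrix holds one microarray intensity per probe and
fraction, with present/absent detection flags.  This module implements
per-chip normalization, the "total probes" filter (at least one present
flag), the inter-fraction correlation structure, pairing of the two series
groups into "slightly different" biological replicates, and the per-probe
variables

* ``I`` — median log2 intensity across fractions (overall expression level),
* ``V`` — Benjamini–Hochberg-adjusted FDR from a one-way ANOVA across
  replicate pairs (non-uniformity of expression across the tissue),

which jointly classify probes into the groups IV / iV / Iv / iv (capital
I: above-median intensity; capital V: significant spatial variance at
FDR < 0.05).

All log transforms are log2(x + 1); the +1 offset stabilizes low
intensities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class FractionDataMatrix:
    """Probe x fraction intensities with present/absent flags."""

    intensity: pd.DataFrame
    present: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensity.index.is_unique:
            dup = self.intensity.index[self.intensity.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe ids: {dup[:5]}")
        if (self.intensity.to_numpy() < 0).any():
            raise ValueError("negative intensities in fraction data")
        if self.present.shape != self.intensity.shape or not (
            self.present.index.equals(self.intensity.index)
            and self.present.columns.equals(self.intensity.columns)
        ):
            raise ValueError("present flags do not align with the intensity matrix")
        self.present = self.present.astype(bool)

    @classmethod
    def from_intensity(
        cls, intensity: pd.DataFrame, present: pd.DataFrame | None = None
    ) -> "FractionDataMatrix":
        if present is None:
            present = pd.DataFrame(
                True, index=intensity.index, columns=intensity.columns
            )
        return cls(intensity=intensity, present=present)

    @property
    def probe_ids(self) -> list[str]:
        return self.intensity.index.tolist()

    @property
    def fraction_ids(self) -> list[str]:
        return self.intensity.columns.tolist()

    @property
    def n_probes(self) -> int:
        return self.intensity.shape[0]


def log2_intensity(matrix: FractionDataMatrix) -> pd.DataFrame:
    return np.log2(matrix.intensity + 1.0)


def normalize_per_chip(
    matrix: FractionDataMatrix, target: str = "p75"
) -> FractionDataMatrix:
    """Scale each fraction (chip) so its 75th-percentile intensity is 1.

    ``target="median"`` scales to the per-chip median instead.  The result
    is scale-free across fractions: multiplying a column by any positive
    constant before normalization does not change the output.
    """
    if target == "p75":
        q = matrix.intensity.quantile(0.75)
    elif target == "median":
        q = matrix.intensity.quantile(0.5)
    else:
        raise ValueError(f"unknown normalization target {target!r}")
    bad = q.index[~(q > 0)].tolist()
    if bad:
        raise ValueError(f"normalization target is zero for fractions: {bad}")
    return FractionDataMatrix(intensity=matrix.intensity / q, present=matrix.present)


def filter_total_probes(matrix: FractionDataMatrix) -> FractionDataMatrix:
    """Keep probes detected ("present") in at least one fraction."""
    keep = matrix.present.any(axis=1)
    return FractionDataMatrix(
        intensity=matrix.intensity.loc[keep], present=matrix.present.loc[keep]
    )


def drop_absent_fractions(matrix: FractionDataMatrix) -> FractionDataMatrix:
    """Drop fractions with no present measurement for any probe.

    Such columns arise when a slab of the design holds no tissue (empty
    oblique end fractions); they carry no information and would make
    correlations undefined.
    """
    keep = matrix.present.any(axis=0)
    return FractionDataMatrix(
        intensity=matrix.intensity.loc[:, keep], present=matrix.present.loc[:, keep]
    )


def fraction_correlations(
    matrix: FractionDataMatrix,
) -> tuple[pd.DataFrame, dict]:
    """Pearson correlations between all fraction pairs on log2 intensities.

    Returns the full correlation matrix and a summary (mean, sem, min, max)
    over the strictly-upper triangle; sem = sd / sqrt(n_pairs).
    """
    if matrix.intensity.shape[1] < 2 or matrix.n_probes < 2:
        raise ValueError("need at least 2 fractions and 2 probes")
    logm = log2_intensity(matrix).to_numpy()
    const = logm.std(axis=0) == 0
    if const.any():
        names = [matrix.fraction_ids[i] for i in np.nonzero(const)[0]]
        raise ValueError(f"correlation undefined for constant fractions: {names}")
    r = np.corrcoef(logm, rowvar=False)
    rdf = pd.DataFrame(r, index=matrix.fraction_ids, columns=matrix.fraction_ids)
    iu = np.triu_indices_from(r, k=1)
    vals = r[iu]
    summary = {
        "mean": float(vals.mean()),
        "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
        "min": float(vals.min()),
        "max": float(vals.max()),
        "n_pairs": int(vals.size),
    }
    return rdf, summary


_FRACTION_ID_RE = re.compile(r"^([A-Za-z]+?)o?(\d+)$")


def _parse_fraction_id(fid: str) -> tuple[str, int]:
    """Split a fraction label into (base series letter, 1-based index).

    The oblique marker 'o' is stripped so that e.g. "Co5" -> ("C", 5) and
    "S3" -> ("S", 3); labels S1 and So1 are anatomical counterparts.
    """
    m = _FRACTION_ID_RE.match(fid)
    if m is None:
        return (fid, 0)
    return (m.group(1), int(m.group(2)))


@dataclass
class ReplicatePairing:
    """Cross-group fraction pairs treated as biological replicates."""

    pairs: list[tuple[str, str, float]]  # (fraction in group A, in group B, r)
    unpaired_a: list[str]
    unpaired_b: list[str]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def pair_replicates(
    matrix: FractionDataMatrix,
    group_a: list[str],
    group_b: list[str],
) -> ReplicatePairing:
    """Pair fractions across the two series groups by correlation.

    Greedy selection of available cross-group pairs by descending Pearson r
    (on log2 intensities).  Ties are broken anatomically: a pair of
    counterpart series (S with So, etc.) is preferred, then the smallest
    fraction-index difference, then label order — so with all correlations
    equal the pairing is S1-So1, S2-So2, ...
    """
    if set(group_a) & set(group_b):
        raise ValueError("replicate groups overlap")
    missing = [f for f in list(group_a) + list(group_b) if f not in matrix.intensity.columns]
    if missing:
        raise ValueError(f"unknown fractions: {missing}")
    logm = log2_intensity(matrix)
    sub = logm[list(group_a) + list(group_b)].to_numpy()
    r = np.corrcoef(sub, rowvar=False)
    na = len(group_a)
    candidates = []
    for i, fa in enumerate(group_a):
        ba, ia = _parse_fraction_id(fa)
        for j, fb in enumerate(group_b):
            bb, ib = _parse_fraction_id(fb)
            penalty = (0 if ba == bb else 1, abs(ia - ib), i, j)
            candidates.append((-r[i, na + j], penalty, fa, fb, r[i, na + j]))
    candidates.sort(key=lambda c: (c[0], c[1]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for _, _, fa, fb, rv in candidates:
        if fa in used_a or fb in used_b:
            continue
        pairs.append((fa, fb, float(rv)))
        used_a.add(fa)
        used_b.add(fb)
    return ReplicatePairing(
        pairs=pairs,
        unpaired_a=[f for f in group_a if f not in used_a],
        unpaired_b=[f for f in group_b if f not in used_b],
    )


def _anova_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA p-values with replicate pairs as levels.

    ``a`` and ``b`` are (probes x pairs) log2 intensities; each pair is a
    level with 2 observations.  Probes with zero within-level variance and
    zero between-level variance (constant everywhere) get p = 1.
    """
    n_pairs = a.shape[1]
    if n_pairs < 2:
        raise ValueError("ANOVA needs at least 2 replicate pairs")
    level_mean = 0.5 * (a + b)
    grand = level_mean.mean(axis=1, keepdims=True)
    ssb = 2.0 * ((level_mean - grand) ** 2).sum(axis=1)
    ssw = 0.5 * ((a - b) ** 2).sum(axis=1)
    dfb, dfw = n_pairs - 1, n_pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = sps.f.sf(f, dfb, dfw)
    p = np.where(ssw == 0, np.where(ssb == 0, 1.0, 0.0), p)
    return p


@dataclass
class ProbeStatsResult:
    """Per-probe I/V variables, group labels and group counts."""

    table: pd.DataFrame  # columns: I, p, V, group
    group_counts: dict[str, int]
    alpha: float

    def iv_correlation(self) -> float:
        """Diagnostic Pearson r between I and log10(V) across probes."""
        v = np.clip(self.table["V"].to_numpy(), 1e-300, None)
        return float(np.corrcoef(self.table["I"].to_numpy(), np.log10(v))[0, 1])


def compute_IV(
    matrix: FractionDataMatrix,
    pairing: ReplicatePairing,
    alpha: float = 0.05,
) -> ProbeStatsResult:
    """Per-probe median intensity (I) and spatial-variance FDR (V).

    ``I`` is the median log2 intensity over *all* fractions.  ``V`` is the
    BH-adjusted p-value of a one-way ANOVA on log2 intensities with each
    replicate pair as a 2-observation level (unpaired fractions are
    excluded from the ANOVA).  Group letters: I if a probe's I exceeds the
    median of all probes' I (ties go to i), V if its FDR < ``alpha``.
    """
    if pairing.n_pairs < 2:
        raise ValueError("need at least 2 replicate pairs")
    logm = log2_intensity(matrix)
    I = logm.median(axis=1).to_numpy()
    a_cols = [p[0] for p in pairing.pairs]
    b_cols = [p[1] for p in pairing.pairs]
    p = _anova_pairs(logm[a_cols].to_numpy(), logm[b_cols].to_numpy())
    v = multipletests(p, method="fdr_bh")[1]
    med_i = float(np.median(I))
    letters_i = np.where(I > med_i, "I", "i")
    letters_v = np.where(v < alpha, "V", "v")
    group = np.char.add(letters_i.astype("U1"), letters_v.astype("U1"))
    table = pd.DataFrame(
        {"I": I, "p": p, "V": v, "group": group}, index=matrix.intensity.index
    )
    counts = {g: int((group == g).sum()) for g in ("IV", "iV", "Iv", "iv")}
    return ProbeStatsResult(table=table, group_counts=counts, alpha=alpha)
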