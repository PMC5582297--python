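"""TMT reporter-ion proteomics: PSM QC, protein summation, differential abundance.

The quantification unit is the peptide-spectrum match (PSM), each carrying
ten reporter-ion intensities (five control channels, five banded).  The
pipeline mirrors a standard isobaric-labeling workflow:

1. identification filters — PSMs are kept only if their precursor mass
   error is below 20 ppm and the peptide maps to exactly one protein;
2. reporter QC — after discarding the single highest and lowest reporter
   intensity, the mean of the remaining eight must exceed 500;
3. protein summation — retained PSM intensities are summed per protein and
   channel, with the number of distinct contributing peptides recorded;
4. channel normalization — total-sum scaling so every channel total equals
   the grand mean total (a transparent substitute for count-model
   normalizers such as edgeR's TMM, adequate for synthetic calibration);
5. differential abundance — per protein, the banded/control ratio of mean
   normalized intensities expressed as a signed fold (ratios below one map
   to the negative reciprocal, e.g. 0.833 -> -1.2), with a two-sample
   pooled t-test on log2 intensities and Benjamini-Hochberg FDR across
   proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fibril_metrics import two_sample_t

CONTROL_CHANNELS = [f"c{i}" for i in range(1, 6)]
BANDED_CHANNELS = [f"b{i}" for i in range(1, 6)]
CHANNELS = CONTROL_CHANNELS + BANDED_CHANNELS

MASS_ERROR_PPM_MAX = 20.0
REPORTER_MEAN_FLOOR = 500.0
PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class DifferentialResult:
    protein_id: str
    fold: float  # signed: |fold| >= 1, sign = direction in banded
    ratio: float  # raw banded/control mean ratio
    p: float
    q: float
    pseudocount_used: bool


def _protein_list(value: str | list[str]) -> list[str]:
    if isinstance(value, str):
        return [p for p in value.split(";") if p]
    return list(value)


def filter_psms(psms: pd.DataFrame) -> pd.DataFrame:
    """Identification filters: |mass error| < 20 ppm, unique protein match."""
    n_prot = psms["protein_ids"].map(lambda v: len(_protein_list(v)))
    keep = (psms["mass_error_ppm"].abs() < MASS_ERROR_PPM_MAX) & (n_prot == 1)
    return psms.loc[keep].copy()


def reporter_qc_mask(psms: pd.DataFrame, floor: float = REPORTER_MEAN_FLOOR) -> pd.Series:
    """Keep mask: trimmed mean of reporters must exceed the floor.

    One maximum and one minimum intensity are dropped per PSM (exactly one
    instance each on ties) and the mean of the remaining eight must be
    strictly greater than ``floor``.
    """
    intens = psms[CHANNELS].to_numpy(dtype=float)
    trimmed = np.sort(intens, axis=1)[:, 1:-1]
    return pd.Series(trimmed.mean(axis=1) > floor, index=psms.index)


def reporter_qc(psms: pd.DataFrame, floor: float = REPORTER_MEAN_FLOOR) -> pd.DataFrame:
    return psms.loc[reporter_qc_mask(psms, floor)].copy()


def sum_to_protein(psms: pd.DataFrame) -> pd.DataFrame:
    """Sum retained PSM intensities per protein and channel.

    Returns a table indexed by protein_id with the ten channel columns and
    ``peptide_count`` (distinct retained peptides).  Input rows must
    already carry a single protein id.
    """
    if len(psms) == 0:
        return pd.DataFrame(columns=CHANNELS + ["peptide_count"]).rename_axis(
            "protein_id"
        )
    df = psms.copy()
    df["protein_id"] = df["protein_ids"].map(lambda v: _protein_list(v)[0])
    sums = df.groupby("protein_id")[CHANNELS].sum()
    peps = df.groupby("protein_id")["peptide_id"].nunique()
    sums["peptide_count"] = peps
    return sums.sort_index()


def normalize_channels(table: pd.DataFrame) -> pd.DataFrame:
    """Total-sum scaling: every channel total becomes the grand-mean total."""
    out = table.copy()
    totals = out[CHANNELS].sum(axis=0)
    if (totals <= 0).any():
        bad = [c for c, t in totals.items() if t <= 0]
        raise ValueError(f"channel total(s) not positive: {bad}")
    out[CHANNELS] = out[CHANNELS] * (totals.mean() / totals)
    return out


def signed_fold(ratio: float) -> float:
    """Map a positive abundance ratio to the signed fold convention.

    Ratios >= 1 are reported as +ratio; ratios < 1 as -1/ratio, so a 0.833
    ratio becomes -1.2.  |fold| is always >= 1.
    """
    if ratio <= 0:
        raise ValueError("abundance ratio must be positive")
    return float(ratio) if ratio >= 1.0 else float(-1.0 / ratio)


def bh_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_abundance(
    table: pd.DataFrame,
    normalize: bool = True,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-protein signed fold change, t-test p and BH q (banded vs control).

    ``table`` is a protein-by-channel sum table as from ``sum_to_protein``.
    Proteins with a zero intensity in any channel get ``pseudocount`` added
    to every channel before the log transform and are flagged.  With
    ``normalize=False`` the input intensities are used as-is, appropriate
    when channels are already calibrated.
    """
    if len(table) == 0:
        return pd.DataFrame(
            columns=["fold", "ratio", "p", "q", "pseudocount_used"]
        ).rename_axis("protein_id")
    work = normalize_channels(table) if normalize else table.copy()
    intens = work[CHANNELS].to_numpy(dtype=float)
    has_zero = (intens <= 0).any(axis=1)
    intens = np.where(has_zero[:, None], intens + pseudocount, intens)

    ctrl = intens[:, : len(CONTROL_CHANNELS)]
    band = intens[:, len(CONTROL_CHANNELS) :]
    ratio = band.mean(axis=1) / ctrl.mean(axis=1)
    folds = np.array([signed_fold(r) for r in ratio])

    log2 = np.log2(intens)
    p = np.empty(len(work))
    for i in range(len(work)):
        a, b = log2[i, 5:], log2[i, :5]
        if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0 and a.mean() != b.mean():
            # perfectly separated noiseless groups: evidence is unbounded
            p[i] = 0.0
        else:
            p[i] = two_sample_t(a, b).p
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "fold": folds,
            "ratio": ratio,
            "p": p,
            "q": q,
            "pseudocount_used": has_zero,
        },
        index=work.index.rename("protein_id"),
    )


def run_quantification(
    psms: pd.DataFrame,
    normalize: bool = True,
    reporter_floor: float = REPORTER_MEAN_FLOOR,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Full PSM-to-differential pipeline; returns (table, results, stage counts)."""
    counts = {"psms_in": int(len(psms))}
    flt = filter_psms(psms)
    counts["after_id_filters"] = int(len(flt))
    qc = reporter_qc(flt, reporter_floor)
    counts["after_reporter_qc"] = int(len(qc))
    table = sum_to_protein(qc)
    counts["proteins_quantified"] = int(len(table))
    results = differential_abundance(table, normalize=normalize)
    return table, results, counts
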