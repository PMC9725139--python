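"""Binding-site strength metrics.

Individual information content of aligned binding sites (Schneider-style R_i,
bits), ChIP peak-intensity ranking via median-subtracted log10 signal-to-noise
(Delta log10 SNR), TF-abundance/TFBS-count ratio summaries, and the
decoy-plasmid copy-number arithmetic used to estimate decoy site counts.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: sentinel for -inf information (zero frequency, zero pseudocount)
NEG_INF_SENTINEL = float("-inf")


class AlignmentError(ValueError):
    """Input sequences are not a valid alignment over ACGT."""


@dataclass
class BindingSiteSet:
    """Aligned binding sites with their frequency matrix and per-site scores."""

    site_ids: list
    sequences: list
    frequency_matrix: np.ndarray  # shape (4, L), rows in ACGT order
    small_sample_correction: float  # e(n), bits
    pseudocount: float
    R_i: Optional[np.ndarray] = None
    autoregulated: Optional[list] = None

    @property
    def length(self) -> int:
        return self.frequency_matrix.shape[1]

    @property
    def n_sites(self) -> int:
        return len(self.sequences)


def small_sample_correction(n: int, alphabet_size: int = 4) -> float:
    """Approximate small-sample entropy correction e(n) = (s-1)/(2 ln2 n) bits."""
    if n <= 0:
        raise AlignmentError("need at least one sequence for e(n)")
    return (alphabet_size - 1) / (2.0 * math.log(2.0) * n)


def _validate_alignment(sequences: Sequence[str]) -> list[str]:
    seqs = [s.upper() for s in sequences]
    if len(seqs) == 0:
        raise AlignmentError("empty site set")
    L = len(seqs[0])
    if L == 0:
        raise AlignmentError("zero-length sites")
    for s in seqs:
        if len(s) != L:
            raise AlignmentError(f"unequal site lengths: {len(s)} vs {L}")
        bad = set(s) - set(ALPHABET)
        if bad:
            raise AlignmentError(f"non-ACGT characters in site: {sorted(bad)}")
    return seqs


def build_pwm(
    sequences: Sequence[str],
    pseudocount: Optional[float] = None,
    correction: bool = True,
    site_ids: Optional[Sequence[str]] = None,
    autoregulated: Optional[Sequence[bool]] = None,
) -> BindingSiteSet:
    """Count-based frequency matrix from aligned sites.

    ``pseudocount`` defaults to 0.5 per base per position for fewer than 50
    sites and 0 otherwise; the e(n) small-sample correction is included unless
    ``correction=False``.
    """
    seqs = _validate_alignment(sequences)
    if len(seqs) < 2:
        raise AlignmentError("need >= 2 aligned sites to build a matrix")
    n, L = len(seqs), len(seqs[0])
    if pseudocount is None:
        pseudocount = 0.5 if n < 50 else 0.0
    if pseudocount < 0:
        raise AlignmentError("pseudocount must be >= 0")
    counts = np.zeros((4, L))
    for s in seqs:
        for j, b in enumerate(s):
            counts[_BASE_INDEX[b], j] += 1.0
    freq = (counts + pseudocount) / (n + 4.0 * pseudocount)
    e_n = small_sample_correction(n) if correction else 0.0
    ids = list(site_ids) if site_ids is not None else [f"site_{i}" for i in range(n)]
    return BindingSiteSet(
        site_ids=ids,
        sequences=seqs,
        frequency_matrix=freq,
        small_sample_correction=e_n,
        pseudocount=pseudocount,
        autoregulated=list(autoregulated) if autoregulated is not None else None,
    )


def individual_information(pwm: BindingSiteSet, sequence: str) -> float:
    """Per-site information R_i = sum_l [2 - e(n) + log2 f(b_l, l)] in bits.

    A zero frequency (possible only with zero pseudocount) yields -inf, which
    is returned as an explicit sentinel rather than being dropped.
    """
    seq = sequence.upper()
    if len(seq) != pwm.length:
        raise AlignmentError(
            f"site length {len(seq)} does not match matrix length {pwm.length}"
        )
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise AlignmentError(f"non-ACGT characters: {sorted(bad)}")
    total = 0.0
    for j, b in enumerate(seq):
        f = pwm.frequency_matrix[_BASE_INDEX[b], j]
        if f == 0.0:
            warnings.warn(
                f"zero frequency for base {b} at position {j}; R_i is -inf"
            )
            return NEG_INF_SENTINEL
        total += 2.0 - pwm.small_sample_correction + math.log2(f)
    return total


def score_sites(pwm: BindingSiteSet) -> BindingSiteSet:
    """Fill ``pwm.R_i`` with the information content of each training site."""
    pwm.R_i = np.array([individual_information(pwm, s) for s in pwm.sequences])
    return pwm


def consensus_sequence(pwm: BindingSiteSet) -> str:
    return "".join(
        ALPHABET[int(i)] for i in np.argmax(pwm.frequency_matrix, axis=0)
    )


def average_information(pwm: BindingSiteSet) -> float:
    """Matrix-average information: sum_l [2 - e(n) + sum_b f log2 f]."""
    f = pwm.frequency_matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    return float(np.sum(2.0 - pwm.small_sample_correction + plogp.sum(axis=0)))


# -- ChIP peak tables --------------------------------------------------------

REQUIRED_PEAK_COLUMNS = ("tf", "peak_id", "snr")
PEAK_ROLES = ("positive", "negative", "unknown", "none")


def delta_log_snr(peaks: pd.DataFrame, low_n: int = 3) -> pd.DataFrame:
    """Median-subtracted log10 peak intensities per TF.

    Adds ``delta_log10_snr``; rows with SNR <= 0 are rejected (count logged).
    TFs with fewer than ``low_n`` surviving peaks are flagged ``low_n=True``.
    """
    for col in REQUIRED_PEAK_COLUMNS:
        if col not in peaks.columns:
            raise ValueError(f"peak table missing column {col!r}")
    df = peaks.copy()
    bad = df["snr"] <= 0
    if bad.any():
        log.warning("rejected %d peaks with non-positive SNR", int(bad.sum()))
        df = df[~bad].copy()
    df["log10_snr"] = np.log10(df["snr"].astype(float))
    df["delta_log10_snr"] = df.groupby("tf")["log10_snr"].transform(
        lambda s: s - s.median()
    )
    df["low_n"] = df.groupby("tf")["snr"].transform("count") < low_n
    return df


def peak_percentile(df: pd.DataFrame, tf: str, peak_id: str) -> float:
    """Percentile (0-1) of one peak's delta among its TF's peaks.

    Fraction of peaks with strictly smaller delta, ties counted half.
    """
    sub = df[df["tf"] == tf]
    if sub.empty:
        raise ValueError(f"no peaks for TF {tf!r}")
    row = sub[sub["peak_id"] == peak_id]
    if row.empty:
        raise ValueError(f"peak {peak_id!r} not found for TF {tf!r}")
    d = float(row["delta_log10_snr"].iloc[0])
    vals = sub["delta_log10_snr"].to_numpy()
    below = float(np.sum(vals < d))
    ties = float(np.sum(vals == d)) - 1.0
    return (below + 0.5 * ties) / max(len(vals) - 1.0, 1.0) if len(vals) > 1 else 0.5


# -- TF/TFBS ratios ----------------------------------------------------------

@dataclass
class RatioSummary:
    ratios: pd.Series
    median: float
    fraction_below_2: float
    fraction_below_4: float
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    counts: np.ndarray = field(default_factory=lambda: np.array([]))
    cumulative_fraction: np.ndarray = field(default_factory=lambda: np.array([]))
    rejected: int = 0


def tf_tfbs_ratios(table: pd.DataFrame, n_bins: int = 20) -> RatioSummary:
    """Per-TF abundance/TFBS-count ratios with histogram and cumulative curve."""
    for col in ("tf", "abundance", "tfbs_count"):
        if col not in table.columns:
            raise ValueError(f"abundance table missing column {col!r}")
    df = table.copy()
    bad = (df["tfbs_count"] < 1) | (df["abundance"] < 0)
    if bad.any():
        log.warning("rejected %d rows (zero TFBS count or negative abundance)", int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise ValueError("no valid rows in abundance table")
    ratios = (df["abundance"] / df["tfbs_count"]).rename("ratio")
    ratios.index = df["tf"].to_numpy()
    logr = np.log10(ratios.to_numpy().clip(min=1e-12))
    edges = np.linspace(logr.min(), logr.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(logr, bins=edges)
    cum = np.cumsum(counts) / len(logr)
    return RatioSummary(
        ratios=ratios,
        median=float(ratios.median()),
        fraction_below_2=float((ratios < 2).mean()),
        fraction_below_4=float((ratios < 4).mean()),
        bin_edges=10.0**edges,
        counts=counts,
        cumulative_fraction=cum,
        rejected=int(bad.sum()),
    )


def decoy_site_count(
    relative_signal: float,
    base_copy_number: float,
    sites_per_plasmid: int,
    clip: bool = False,
) -> tuple[int, int]:
    """Decoy TFBS count from a relative plasmid signal.

    Copy number = round(relative_signal * base_copy_number); decoy count =
    copy number * sites_per_plasmid.  Returns (copy_number, decoy_count).
    """
    if relative_signal <= 0:
        raise ValueError("relative_signal must be > 0")
    if relative_signal > 1:
        warnings.warn(f"relative_signal {relative_signal} > 1")
        if clip:
            relative_signal = 1.0
    if base_copy_number < 0 or sites_per_plasmid < 0:
        raise ValueError("counts must be >= 0")
    copy_number = int(round(relative_signal * base_copy_number))
    return copy_number, copy_number * int(sites_per_plasmid)
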