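"""Deterministic synthetic fixtures and shared file IO.

Every generator is a pure function of its arguments plus an integer seed, so
identical calls produce byte-identical files.  FASTA goes through Biopython,
tables through pandas with a fixed tab-separated dialect.
"""

from __future__ import annotations

import io
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import qmc

from .core_params import ConfigurationError, SystemParams, normalize_params
from .site_analysis import ALPHABET

log = logging.getLogger(__name__)

FASTA_WRAP = 60


# -- generators --------------------------------------------------------------

def generate_pwm_sites(
    consensus: str,
    n: int,
    mutation_prob: float,
    seed: int,
) -> tuple[list[str], np.ndarray]:
    """n aligned sites derived from a consensus by per-position substitution.

    Each position mutates independently with probability ``mutation_prob`` to a
    uniformly chosen different base.  Returns (sites, true_matrix) where the
    true matrix holds the generating per-base probabilities, rows in ACGT order.
    """
    consensus = consensus.upper()
    if not consensus or set(consensus) - set(ALPHABET):
        raise ValueError("consensus must be nonempty over ACGT")
    if not 0 <= mutation_prob < 0.75:
        raise ValueError("mutation_prob must be in [0, 0.75)")
    rng = np.random.default_rng(seed)
    L = len(consensus)
    sites = []
    for _ in range(n):
        chars = list(consensus)
        hits = rng.random(L) < mutation_prob
        for j in np.where(hits)[0]:
            others = [b for b in ALPHABET if b != consensus[j]]
            chars[j] = others[rng.integers(3)]
        sites.append("".join(chars))
    true = np.full((4, L), mutation_prob / 3.0)
    for j, b in enumerate(consensus):
        true[ALPHABET.index(b), j] = 1.0 - mutation_prob
    return sites, true


def generate_peak_table(
    n_peaks: int,
    lognormal_mu: float = 2.0,
    lognormal_sigma: float = 0.5,
    spike_quantile: float = 0.9,
    seed: int = 0,
    tf: str = "synthTF",
) -> tuple[pd.DataFrame, dict]:
    """Lognormal SNR peak table with one autoregulated peak at a known quantile.

    Returns (table, metadata); metadata records the ground-truth quantile of
    the flagged peak among all peaks.
    """
    if n_peaks < 3:
        raise ValueError("need n_peaks >= 3")
    if not 0 <= spike_quantile <= 1:
        raise ValueError("spike_quantile must be in [0, 1]")
    rng = np.random.default_rng(seed)
    snr = 10.0 ** rng.normal(lognormal_mu, lognormal_sigma, n_peaks - 1)
    spike = float(np.quantile(snr, spike_quantile))
    if spike_quantile >= 1.0:
        spike = float(snr.max() * 1.01)
    df = pd.DataFrame(
        {
            "tf": tf,
            "peak_id": [f"peak_{i:04d}" for i in range(n_peaks - 1)] + ["autoreg"],
            "snr": np.concatenate([snr, [spike]]),
            "role": ["none"] * (n_peaks - 1) + ["positive"],
        }
    )
    truth_quantile = float(np.mean(df["snr"].to_numpy() < spike))
    meta = {
        "n_peaks": n_peaks,
        "lognormal_mu": lognormal_mu,
        "lognormal_sigma": lognormal_sigma,
        "spike_quantile": spike_quantile,
        "seed": seed,
        "true_quantile_of_autoregulated_peak": truth_quantile,
    }
    return df, meta


def generate_abundance_table(
    n_tfs: int,
    fraction_below_2: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """TF abundance/TFBS-count table with a controlled fraction of ratios < 2."""
    if n_tfs < 1:
        raise ValueError("need n_tfs >= 1")
    rng = np.random.default_rng(seed)
    n_low = int(round(fraction_below_2 * n_tfs))
    ratios = np.concatenate(
        [
            rng.uniform(0.1, 1.999, n_low),
            10.0 ** rng.uniform(np.log10(2.001), 2.0, n_tfs - n_low),
        ]
    )
    rng.shuffle(ratios)
    counts = rng.integers(1, 50, n_tfs)
    return pd.DataFrame(
        {
            "tf": [f"TF{i:03d}" for i in range(n_tfs)],
            "abundance": ratios * counts,
            "tfbs_count": counts,
        }
    )


def generate_param_grid(
    ranges: dict,
    n: int,
    seed: int = 0,
    method: str = "lhs",
) -> pd.DataFrame:
    """Parameter sets sampled from per-field [lo, hi] ranges.

    ``method="lhs"`` draws a Latin hypercube in log space; ``method="grid"``
    uses a log-spaced full factorial (n points per axis).  Single-point ranges
    collapse to their value.
    """
    if not ranges:
        raise ConfigurationError("empty parameter ranges")
    names = sorted(ranges)
    los, his = [], []
    for name in names:
        lo, hi = ranges[name]
        if lo > hi:
            raise ConfigurationError(f"inverted range for {name}: [{lo}, {hi}]")
        if lo <= 0:
            raise ConfigurationError(f"range for {name} must be positive")
        los.append(lo)
        his.append(hi)
    los, his = np.array(los), np.array(his)
    if method == "lhs":
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        u = sampler.random(n)
        vals = np.exp(np.log(los) + u * (np.log(his) - np.log(los)))
    elif method == "grid":
        axes = [np.geomspace(lo, hi, n) if hi > lo else np.full(n, lo)
                for lo, hi in zip(los, his)]
        mesh = np.meshgrid(*axes, indexing="ij")
        vals = np.column_stack([m.ravel() for m in mesh])
        vals = np.unique(vals, axis=0)
    else:
        raise ConfigurationError(f"unknown sampling method {method!r}")
    return pd.DataFrame(vals, columns=names)


# -- IO ----------------------------------------------------------------------

def write_fasta(path, sites: Sequence[str], ids: Sequence[str],
                autoregulated: Optional[Sequence[bool]] = None) -> None:
    records = []
    for i, (sid, seq) in enumerate(zip(ids, sites)):
        desc = ""
        if autoregulated is not None and autoregulated[i]:
            desc = "autoregulated=true"
        records.append(SeqRecord(Seq(seq), id=sid, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(records)


def read_fasta_sites(path) -> tuple[list[str], list[str], list[bool]]:
    """Aligned sites from FASTA; returns (ids, sequences, autoregulated flags)."""
    ids, seqs, flags = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
        flags.append("autoregulated=true" in rec.description.lower())
    if not seqs:
        raise ConfigurationError(f"no sequences found in {path}")
    return ids, seqs, flags


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(path, **fields) -> None:
    """JSON sidecar recording parameters, seed and assumptions of a run."""
    payload = dict(fields)
    payload.setdefault("format_version", 1)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def load_config(path, overrides: Optional[dict] = None) -> SystemParams:
    """SystemParams from a YAML/JSON config file, with CLI overrides on top.

    Keys may be starred field names (taken verbatim) or raw dimensional names
    together with ``K_auto`` (normalized at load).
    """
    text = Path(path).read_text()
    data = yaml.safe_load(io.StringIO(text))
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    data = {k: v for k, v in data.items() if not isinstance(v, dict)}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    raw_keys = {"D", "K", "Cp", "Ct", "Rb"}
    if raw_keys & set(data):
        k_auto = data.pop("K_auto", None)
        if k_auto is None:
            raise ConfigurationError(
                "dimensional parameters require K_auto in the config"
            )
        return normalize_params(data, k_auto)
    return SystemParams(**data)


def load_full_model_section(path) -> Optional[dict]:
    """Optional ``full_model`` subsection of a config file (elementary rates)."""
    data = yaml.safe_load(Path(path).read_text())
    if isinstance(data, dict) and isinstance(data.get("full_model"), dict):
        return data["full_model"]
    return None
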