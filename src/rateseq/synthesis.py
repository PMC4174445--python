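"""Steady-state synthesis rates from decay constants and abundances.

At steady state dRNA/dt = 0, so synthesis balances removal:
k = alpha * [mRNA], in mRNAs per cell per minute.  In a dividing culture
removal includes dilution, so the default uses the total rate
(alpha_rna + alpha_growth); ``mode="rna_only"`` uses degradation alone.
Abundances are user-supplied (this assay does not quantify absolute
abundance); relative abundances can be scaled to a per-cell total, 60,000
mRNAs/cell being the conventional budding-yeast figure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import KineticEstimate

__all__ = ["SynthesisEstimate", "synthesis_rate", "scale_abundances", "synthesis_all"]


@dataclass
class SynthesisEstimate:
    """Per-transcript synthesis rate k (mRNAs cell^-1 min^-1) with CI."""

    transcript_id: str
    k: float = float("nan")
    k_ci_low: float = float("nan")
    k_ci_high: float = float("nan")
    abundance_used: float = float("nan")


def synthesis_rate(
    est: KineticEstimate, abundance: float, mode: str = "total"
) -> SynthesisEstimate:
    """k = alpha * abundance, CI bounds propagated from the alpha CI.

    ``mode="total"`` uses alpha_rna + alpha_growth (removal = degradation +
    dilution); ``mode="rna_only"`` uses alpha_rna.  The CI shifts by the
    same alpha offset in either mode.
    """
    if not est.converged:
        raise ValueError(f"{est.transcript_id}: cannot compute k for a non-converged fit")
    if abundance < 0:
        raise ValueError("abundance must be non-negative")
    if mode == "total":
        shift = 0.0
        alpha = est.alpha_total
    elif mode == "rna_only":
        shift = est.alpha_total - est.alpha_rna
        alpha = est.alpha_rna
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SynthesisEstimate(
        transcript_id=est.transcript_id,
        k=alpha * abundance,
        k_ci_low=(est.ci_low - shift) * abundance,
        k_ci_high=(est.ci_high - shift) * abundance,
        abundance_used=abundance,
    )


def scale_abundances(relative_abundance: pd.Series, total_per_cell: float) -> pd.Series:
    """Scale relative abundances so they sum to ``total_per_cell`` mRNAs/cell."""
    frac = pd.Series(relative_abundance, dtype=float)
    if (frac < 0).any():
        raise ValueError("relative abundances must be non-negative")
    s = frac.sum()
    if s <= 0:
        raise ValueError("relative abundances sum to zero")
    return frac / s * float(total_per_cell)


def synthesis_all(
    estimates: list[KineticEstimate],
    abundances: pd.Series,
    mode: str = "total",
) -> dict[str, SynthesisEstimate]:
    """Synthesis rates for every converged transcript with an abundance.

    Transcripts missing from ``abundances`` (or non-converged) get an
    all-NaN estimate so downstream joins stay stable.
    """
    out: dict[str, SynthesisEstimate] = {}
    for est in estimates:
        tid = est.transcript_id
        if est.converged and tid in abundances.index and np.isfinite(abundances[tid]):
            out[tid] = synthesis_rate(est, float(abundances[tid]), mode)
        else:
            out[tid] = SynthesisEstimate(transcript_id=tid)
    return out
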