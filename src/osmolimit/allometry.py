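"""Allometric cell element quotas.

Cellular nitrogen content follows the base-10 allometric regression on
biovolume,  pg N = 10**(-1.084 + 0.837*log10(BV)),  converted to
nmol N cell^-1 with the molar mass of N.  The phosphorus quota is tied to
nitrogen through the canonical Redfield N:P of 16 (P_cell = N_cell/16).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "LOG10_INTERCEPT",
    "LOG10_SLOPE",
    "N_MOLAR_MASS",
    "REDFIELD_NP",
    "CellQuota",
    "n_content",
    "p_content",
    "cell_quota",
]

LOG10_INTERCEPT = -1.084  # log10 pg N at BV = 1 um^3
LOG10_SLOPE = 0.837  # dimensionless allometric exponent
N_MOLAR_MASS = 14.007  # g mol^-1
REDFIELD_NP = 16.0


@dataclass(frozen=True)
class CellQuota:
    """Per-cell nitrogen and phosphorus content (nmol cell^-1)."""

    n_content: float
    p_content: float


def _check_biovolume(biovolume) -> np.ndarray:
    bv = np.asarray(biovolume, dtype=float)
    if np.any(~np.isfinite(bv)) or np.any(bv <= 0):
        raise DomainError("biovolume must be finite and > 0 um^3")
    return bv


def n_content(biovolume):
    """Nitrogen quota (nmol N cell^-1) for a biovolume (um^3); accepts arrays."""
    bv = _check_biovolume(biovolume)
    pg_n = 10.0 ** (LOG10_INTERCEPT + LOG10_SLOPE * np.log10(bv))
    out = pg_n / N_MOLAR_MASS / 1000.0  # pg -> pmol -> nmol
    return float(out) if np.isscalar(biovolume) else out


def p_content(biovolume):
    """Phosphorus quota (nmol P cell^-1): exactly n_content/16."""
    return n_content(biovolume) / REDFIELD_NP


def cell_quota(biovolume: float) -> CellQuota:
    n = n_content(float(biovolume))
    return CellQuota(n_content=n, p_content=n / REDFIELD_NP)
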