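"""Spindle and slow oscillation maturity scores.

Fast-spindle maturity quantifies how closely the individually dominant
(development-specific) fast centro-parietal spindle resembles the adult
canonical 12.5-16 Hz spindle: raw scores are adult-like minus
development-specific differences in density and amplitude, and the
*negated* frequency difference (a small frequency gap means high
maturity).  SO maturity is the frontal minus centro-parietal SO amplitude
difference (frontal dominance is the mature pattern).  Raw scores are
Z-transformed across all recordings and compressed into one latent
spindle-maturity component (first principal component, oriented so higher
values mean higher maturity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import FeatureSummary

RAW_COLUMNS = ("freq_maturity_raw", "density_maturity_raw", "amp_maturity_raw")
Z_COLUMNS = ("freq_maturity_z", "density_maturity_z", "amp_maturity_z")


def spindle_maturity_raw(
    adult_like: FeatureSummary, dev_specific: FeatureSummary
) -> tuple[float, float, float]:
    """(freq, density, amp) raw maturity scores.

    Frequency difference is sign-inverted: development-specific peaks far
    below the adult-like event frequency yield strongly negative scores.
    Missing features (no events of a class) propagate as NaN.
    """
    freq = -(adult_like.frequency_hz - dev_specific.frequency_hz)
    density = adult_like.density_per_min - dev_specific.density_per_min
    amp = adult_like.amplitude_uv - dev_specific.amplitude_uv
    return float(freq), float(density), float(amp)


def so_maturity_raw(frontal_amp_uv: float, centroparietal_amp_uv: float) -> float:
    """Frontal minus centro-parietal SO amplitude (µV); negative values
    mark the posterior-dominant, immature topography."""
    if not np.isfinite(frontal_amp_uv) or not np.isfinite(centroparietal_amp_uv):
        raise ValueError("both SO amplitudes must be present")
    return float(frontal_amp_uv - centroparietal_amp_uv)


def zscore_columns(table: pd.DataFrame, columns=RAW_COLUMNS + ("so_maturity_raw",)) -> pd.DataFrame:
    """Append ``*_z`` columns: (x - mean)/SD with the sample SD, computed
    across all non-missing rows of the table."""
    out = table.copy()
    for col in columns:
        x = out[col].astype(float)
        valid = x.notna()
        if valid.sum() < 2:
            raise ValueError(f"column {col!r} needs >= 2 non-missing rows")
        sd = x[valid].std(ddof=1)
        if sd == 0:
            raise ValueError(f"column {col!r} has zero variance")
        out[col.replace("_raw", "") + "_z"] = (x - x[valid].mean()) / sd
    return out


@dataclass
class PCAResult:
    scores: np.ndarray  # aligned to the input rows, NaN for excluded rows
    loadings: np.ndarray  # unit-norm first eigenvector
    explained_ratio: float
    eigenvalues: np.ndarray


def maturity_component(z_table: pd.DataFrame, columns=Z_COLUMNS) -> PCAResult:
    """First principal component of the Z-scored maturity variables.

    Scores are projections onto the unit-norm first eigenvector of the
    covariance of the (already standardized) columns, sign-oriented so the
    loading on ``freq_maturity_z`` is positive: higher component values
    indicate higher fast-spindle maturity.  Rows with missing values are
    excluded from the decomposition and receive NaN scores.
    """
    Z = z_table[list(columns)].to_numpy(float)
    valid = np.all(np.isfinite(Z), axis=1)
    Zv = Z[valid]
    if Zv.shape[0] < 2:
        raise ValueError("need >= 2 complete rows for PCA")
    cov = np.cov(Zv, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    v = eigvecs[:, order[0]]
    # orient: positive loading on the frequency-maturity indicator
    i_freq = list(columns).index("freq_maturity_z") if "freq_maturity_z" in columns else 0
    if v[i_freq] < 0 or (v[i_freq] == 0 and v.sum() < 0):
        v = -v
    scores = np.full(Z.shape[0], np.nan)
    scores[valid] = Zv @ v
    total = eigvals.sum()
    return PCAResult(
        scores=scores,
        loadings=v,
        explained_ratio=float(eigvals[0] / total) if total > 0 else float("nan"),
        eigenvalues=eigvals,
    )


def build_maturity_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble the per-recording maturity table, Z-transform the raw
    scores and attach the PCA spindle-maturity component.

    Each row dict needs: subject_id, timepoint, the adult-like and
    development-specific :class:`FeatureSummary` objects under keys
    ``adult_like``/``dev_specific``, and frontal/centro-parietal SO
    amplitudes under ``so_amp_frontal_uv``/``so_amp_centroparietal_uv``.
    """
    records = []
    for row in rows:
        freq, density, amp = spindle_maturity_raw(row["adult_like"], row["dev_specific"])
        records.append(
            {
                "subject_id": row["subject_id"],
                "timepoint": row.get("timepoint", 1),
                "freq_maturity_raw": freq,
                "density_maturity_raw": density,
                "amp_maturity_raw": amp,
                "so_maturity_raw": so_maturity_raw(
                    row["so_amp_frontal_uv"], row["so_amp_centroparietal_uv"]
                ),
            }
        )
    table = zscore_columns(pd.DataFrame(records))
    pca = maturity_component(table)
    table["spindle_maturity_component"] = pca.scores
    table.attrs["pca_loadings"] = pca.loadings
    table.attrs["pca_explained_ratio"] = pca.explained_ratio
    return table
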