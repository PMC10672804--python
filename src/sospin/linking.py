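"""Linking maturity to coupling: PLSC and the gamma modulation GLMM.

Partial least squares correlation (PLSC) decomposes the cross-block
correlation matrix between the three spindle-maturity scores and the
vectorized SO-locked time-frequency t-maps by SVD; dimensions are
assessed with a permutation test on the singular values and the
reliability of each pixel weight with bootstrap ratios (BSR, weight over
bootstrap SE; |BSR| > 1.96 is conventionally stable).

The modulation model is a log-linked gamma GLMM of the KL-divergence
coupling index on the spindle-maturity component with the SO-maturity
score as covariate and a random intercept per participant; estimation is
delegated to lme4::glmer (bobyqa optimizer) through Rscript — this module
owns only the model specification, validation and result extraction.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

BSR_STABLE = 1.96


@dataclass
class PLSCResult:
    singular_values: np.ndarray
    perm_p: np.ndarray
    x_saliences: np.ndarray  # (3, n_dims)
    x_salience_ci: np.ndarray  # (3, n_dims, 2) bootstrap percentile 95% CI
    x_latent_corr: np.ndarray  # corr(latent Y score, raw X columns), (3, n_dims)
    x_latent_corr_ci: np.ndarray  # (3, n_dims, 2)
    y_saliences: np.ndarray  # (p, n_dims)
    y_bsr: np.ndarray  # (p, n_dims)
    n_perm: int
    n_boot: int


def _standardize(M: np.ndarray, name: str) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(f"constant column in {name}; cannot standardize")
    return (M - M.mean(axis=0)) / sd


def _cross_corr(Xs: np.ndarray, Ys: np.ndarray) -> np.ndarray:
    return Xs.T @ Ys / (Xs.shape[0] - 1)


def plsc(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 5000,
    n_boot: int = 5000,
    seed: int | np.random.Generator | None = None,
) -> PLSCResult:
    """PLSC between maturity scores ``X`` (n x 3) and vectorized t-maps
    ``Y`` (n x p).

    Permutation p per dimension is ``(1 + #{perm S_d >= S_d}) / (n_perm + 1)``
    with rows of X re-paired against Y.  Bootstrap resamples subjects with
    replacement; each resample's singular vectors are sign-aligned to the
    original solution before accumulating SEs and percentile CIs.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    n = X.shape[0]
    if n < 10:
        raise ValueError("PLSC needs at least 10 subjects")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(Y)):
        raise ValueError("missing values in X or Y")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Xs = _standardize(X, "X")
    Ys = _standardize(Y, "Y")
    R = _cross_corr(Xs, Ys)
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    n_dims = S.size

    # permutation test on singular values
    exceed = np.zeros(n_dims)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Sp = np.linalg.svd(_cross_corr(Xs[perm], Ys), compute_uv=False)
        exceed += Sp >= S
    perm_p = (1.0 + exceed) / (n_perm + 1.0)

    # bootstrap for salience stability
    latent_y = Ys @ V  # (n, n_dims)
    boot_U = np.empty((n_boot, *U.shape))
    boot_V_sq_acc = np.zeros_like(V)
    boot_V_acc = np.zeros_like(V)
    boot_corr = np.empty((n_boot, X.shape[1], n_dims))
    b = 0
    attempts = 0
    while b < n_boot and attempts < 20 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        Xb, Yb = X[idx], Y[idx]
        if np.any(Xb.std(axis=0) == 0) or np.any(Yb.std(axis=0) == 0):
            continue  # degenerate resample; redraw
        Xbs = _standardize(Xb, "X")
        Ybs = _standardize(Yb, "Y")
        Ub, Sb, Vbt = np.linalg.svd(_cross_corr(Xbs, Ybs), full_matrices=False)
        Vb = Vbt.T
        # sign alignment against the original vectors
        flips = np.sign(np.einsum("pd,pd->d", Vb, V) + 1e-300)
        Ub = Ub * flips
        Vb = Vb * flips
        boot_U[b] = Ub
        boot_V_acc += Vb
        boot_V_sq_acc += Vb**2
        ly = Ybs @ Vb
        for d in range(n_dims):
            sd_ly = ly[:, d].std(ddof=1)
            for j in range(X.shape[1]):
                sx = Xb[:, j].std(ddof=1)
                boot_corr[b, j, d] = (
                    np.corrcoef(ly[:, d], Xb[:, j])[0, 1] if sd_ly > 0 and sx > 0 else np.nan
                )
        b += 1
    if b < n_boot:
        raise ValueError("too many degenerate bootstrap resamples")

    v_mean = boot_V_acc / n_boot
    v_se = np.sqrt(np.maximum(boot_V_sq_acc / n_boot - v_mean**2, 0.0) * n_boot / (n_boot - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        y_bsr = np.where(v_se > 0, V / v_se, np.inf * np.sign(V))

    x_ci = np.stack(
        [np.percentile(boot_U, 2.5, axis=0), np.percentile(boot_U, 97.5, axis=0)], axis=-1
    )
    corr_obs = np.empty((X.shape[1], n_dims))
    for d in range(n_dims):
        for j in range(X.shape[1]):
            corr_obs[j, d] = np.corrcoef(latent_y[:, d], X[:, j])[0, 1]
    corr_ci = np.stack(
        [
            np.nanpercentile(boot_corr, 2.5, axis=0),
            np.nanpercentile(boot_corr, 97.5, axis=0),
        ],
        axis=-1,
    )
    return PLSCResult(
        singular_values=S,
        perm_p=perm_p,
        x_saliences=U,
        x_salience_ci=x_ci,
        x_latent_corr=corr_obs,
        x_latent_corr_ci=corr_ci,
        y_saliences=V,
        y_bsr=y_bsr,
        n_perm=n_perm,
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# gamma GLMM
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    coefficients: pd.DataFrame  # term, estimate, std_error, t_value, p_value
    family: str
    link: str
    random_structure: str
    converged: bool
    messages: list[str]

    def coef(self, term: str) -> float:
        row = self.coefficients[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(f"no coefficient {term!r}")
        return float(row["estimate"].iloc[0])


_R_TEMPLATE = """
suppressMessages(library(lme4))
dat <- read.csv("{data}")
dat$subject_id <- factor(dat$subject_id)
msgs <- character(0)
fit <- withCallingHandlers(
  glmer({formula}, data = dat, family = Gamma(link = "log"),
        control = glmerControl(optimizer = "bobyqa")),
  warning = function(w) {{ msgs <<- c(msgs, conditionMessage(w)); invokeRestart("muffleWarning") }}
)
co <- summary(fit)$coefficients
out <- list(
  terms = rownames(co),
  estimate = unname(co[, 1]),
  std_error = unname(co[, 2]),
  t_value = unname(co[, 3]),
  p_value = unname(co[, 4]),
  messages = msgs,
  converged = length(fit@optinfo$conv$lme4$messages) == 0
)
writeLines(jsonlite::toJSON(out, auto_unbox = TRUE, digits = 12), "{out}")
"""


def fit_modulation_model(
    table: pd.DataFrame,
    response: str = "kl",
    predictor: str = "spindle_maturity_component",
    covariates: tuple[str, ...] = ("so_maturity_z",),
    subject_col: str = "subject_id",
) -> ModelResult:
    """Fit ``kl ~ maturity + covariates + (1 | subject)`` with a gamma
    family and log link via lme4::glmer.

    Raises on non-positive responses (outside the gamma support) and
    reports convergence problems explicitly instead of hiding them.
    """
    needed = [response, predictor, *covariates, subject_col]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    bad = table.index[table[response] <= 0].tolist()
    if bad:
        raise ValueError(
            f"{response} must be strictly positive for a gamma model; offending rows: {bad}"
        )
    if shutil.which("Rscript") is None:
        raise RuntimeError("Rscript not found; gamma GLMM estimation requires R with lme4")

    fixed = " + ".join([predictor, *covariates])
    formula = f"{response} ~ {fixed} + (1 | {subject_col})"
    with tempfile.TemporaryDirectory() as tmp:
        data_path = Path(tmp) / "data.csv"
        out_path = Path(tmp) / "fit.json"
        table[needed].to_csv(data_path, index=False)
        script = _R_TEMPLATE.format(data=data_path, formula=formula, out=out_path)
        script_path = Path(tmp) / "fit.R"
        script_path.write_text(script)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script_path)], capture_output=True, text=True
        )
        if proc.returncode != 0 or not out_path.exists():
            raise RuntimeError(f"glmer fit failed:\n{proc.stderr.strip()}")
        payload = json.loads(out_path.read_text())

    terms = payload["terms"] if isinstance(payload["terms"], list) else [payload["terms"]]

    def as_list(x):
        return x if isinstance(x, list) else [x]

    coefficients = pd.DataFrame(
        {
            "term": terms,
            "estimate": as_list(payload["estimate"]),
            "std_error": as_list(payload["std_error"]),
            "t_value": as_list(payload["t_value"]),
            "p_value": as_list(payload["p_value"]),
        }
    )
    messages = payload.get("messages", [])
    if isinstance(messages, str):
        messages = [messages]
    return ModelResult(
        coefficients=coefficients,
        family="gamma",
        link="log",
        random_structure=f"intercept per {subject_col}",
        converged=bool(payload.get("converged", True)),
        messages=list(messages),
    )
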