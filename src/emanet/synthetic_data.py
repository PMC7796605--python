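"""Synthetic EMA data with known multilevel VAR(1) structure.

The generator is the mirror image of the estimator: each person i has a
latent mean vector mu_i drawn from a between-person covariance, and their
occasion-to-occasion dynamics follow a person-mean-centered VAR(1)

    y_t = mu_i + B (y_{t-1} - mu_i) + eps_t,     eps_t ~ MVN(0, s^2 * Theta^{-1})

so that all three estimable networks have exact ground truths:

* temporal network      — the coefficient matrix B (row = outcome at t,
  column = predictor at t-1; diagonal = autoregression),
* contemporaneous network — the partial correlations implied by the
  residual precision matrix Theta (pcor_jk = -Theta_jk / sqrt(Theta_jj Theta_kk)),
* between-subject network — the partial correlations of the person means,
  implied by Sigma_between.

The process iterates across *all* occasions in temporal order, including
day boundaries; only the estimator later discards overnight lags.  A
burn-in is discarded so recorded series start near stationarity.
Missingness is applied at the beep level (whole occasions missing
completely at random, emulating expired prompts), plus extra
item-level missingness for a skippable eating item (no eating episode).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .ema_data import BeepSchedule, EMADataset, ItemSpec, stress_affect_eating_items

__all__ = [
    "SimulationTruth",
    "SimulationConfig",
    "make_truth",
    "empty_truth",
    "simulate_dataset",
]

#: Iterations discarded before the first recorded occasion.
BURN_IN = 50

#: Spectral-radius ceiling enforced on generated temporal matrices.
MAX_SPECTRAL_RADIUS = 0.9

#: Minimum eigenvalue kept when sparsifying a precision matrix.
MIN_PRECISION_EIG = 0.05


class GenerationError(ValueError):
    """A requested truth cannot be made stationary / positive definite."""


def _spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(a))))


def _is_spd(a: np.ndarray, tol: float = 1e-10) -> bool:
    if not np.allclose(a, a.T, atol=1e-8):
        return False
    try:
        np.linalg.cholesky(a + tol * np.eye(len(a)))
        return True
    except np.linalg.LinAlgError:
        return False


@dataclass
class SimulationTruth:
    """Ground-truth parameters of the generative multilevel VAR(1)."""

    item_names: list[str]
    B: np.ndarray
    Theta: np.ndarray
    Sigma_between: np.ndarray
    mu: np.ndarray
    noise_scale: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        m = len(self.item_names)
        self.B = np.asarray(self.B, dtype=float)
        self.Theta = np.asarray(self.Theta, dtype=float)
        self.Sigma_between = np.asarray(self.Sigma_between, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        for name, a in [("B", self.B), ("Theta", self.Theta), ("Sigma_between", self.Sigma_between)]:
            if a.shape != (m, m):
                raise GenerationError(f"{name} must be {m}x{m}, got {a.shape}")
        if self.mu.shape != (m,):
            raise GenerationError(f"mu must have length {m}")
        if _spectral_radius(self.B) >= 1.0:
            raise GenerationError(
                f"temporal matrix is non-stationary (spectral radius "
                f"{_spectral_radius(self.B):.3f} >= 1)"
            )
        if not _is_spd(self.Theta):
            raise GenerationError("Theta must be symmetric positive definite")
        if not _is_spd(self.Sigma_between):
            raise GenerationError("Sigma_between must be symmetric positive definite")

    @property
    def m(self) -> int:
        return len(self.item_names)

    def contemporaneous_pcor(self) -> np.ndarray:
        """True contemporaneous partial correlations implied by Theta."""
        d = np.sqrt(np.diag(self.Theta))
        pcor = -self.Theta / np.outer(d, d)
        np.fill_diagonal(pcor, 0.0)
        return pcor

    def between_pcor(self) -> np.ndarray:
        """True between-subject partial correlations implied by Sigma_between."""
        prec = np.linalg.inv(self.Sigma_between)
        d = np.sqrt(np.diag(prec))
        pcor = -prec / np.outer(d, d)
        np.fill_diagonal(pcor, 0.0)
        return pcor

    # -- serialisation ---------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "item_names": self.item_names,
            "B": self.B.tolist(),
            "Theta": self.Theta.tolist(),
            "Sigma_between": self.Sigma_between.tolist(),
            "mu": self.mu.tolist(),
            "noise_scale": self.noise_scale,
            "seed": self.seed,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SimulationTruth":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            try:
                doc = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    doc = json.load(fh)
        return cls(
            item_names=list(doc["item_names"]),
            B=np.asarray(doc["B"]),
            Theta=np.asarray(doc["Theta"]),
            Sigma_between=np.asarray(doc["Sigma_between"]),
            mu=np.asarray(doc["mu"]),
            noise_scale=float(doc["noise_scale"]),
            seed=doc.get("seed"),
        )


@dataclass
class SimulationConfig:
    """Study-design side of a simulation.

    Defaults emulate the motivating study design: 84 persons, 4 beeps/day
    for 14 days, roughly 15% of beeps missed outright, and the eating item
    additionally missing on about 22% of answered beeps (no eating episode
    in the preceding interval).
    """

    n_persons: int = 84
    schedule: BeepSchedule = field(default_factory=BeepSchedule)
    missing_beep_rate: float = 0.15
    eating_item_missing_rate: float = 0.223
    seed: int = 0
    clip_to_range: bool = False
    burn_in: int = BURN_IN

    def __post_init__(self) -> None:
        if not 0 <= self.missing_beep_rate < 1:
            raise ValueError("missing_beep_rate must be in [0, 1)")
        if not 0 <= self.eating_item_missing_rate < 1:
            raise ValueError("eating_item_missing_rate must be in [0, 1)")
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"] = asdict(self.schedule)
        return d


def _sparse_precision(
    m: int, density: float, low: float, high: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-diagonal precision matrix with sparse signed off-diagonals.

    Off-diagonal partial correlations are drawn with magnitude in
    [low, high]; if the implied matrix is not sufficiently positive
    definite the off-diagonal block is shrunk uniformly (pattern and signs
    preserved).
    """
    w = np.zeros((m, m))
    iu = np.triu_indices(m, 1)
    keep = rng.random(len(iu[0])) < density
    vals = rng.uniform(low, high, len(iu[0])) * rng.choice([-1.0, 1.0], len(iu[0]))
    w[iu] = np.where(keep, vals, 0.0)
    w = w + w.T
    # precision = I - W  (so true pcor_jk = W_jk while the diagonal is 1)
    lam = np.max(np.abs(np.linalg.eigvalsh(w))) if np.any(w) else 0.0
    if lam >= 1.0 - MIN_PRECISION_EIG:
        w *= (1.0 - MIN_PRECISION_EIG) / lam * 0.999
    return np.eye(m) - w


def make_truth(
    m: int,
    edge_density: float = 0.3,
    weight_low: float = 0.1,
    weight_high: float = 0.3,
    seed: int = 0,
    item_names: list[str] | None = None,
    mu: np.ndarray | float = 50.0,
    noise_scale: float = 18.0,
    between_sd: float = 12.0,
) -> SimulationTruth:
    """Draw a random sparse ground truth.

    Temporal matrix: every diagonal (autoregressive) entry is present with
    a positive weight in [weight_low, weight_high]; each off-diagonal entry
    is present with probability ``edge_density`` and a signed weight of
    magnitude in the same range; the matrix is rescaled if its spectral
    radius exceeds 0.9.  Contemporaneous and between-subject structures are
    sparse unit-diagonal precision matrices built the same way, so their
    true partial correlations equal the drawn weights (up to a uniform
    shrink recorded only implicitly in the matrices themselves).

    ``mu``, ``noise_scale`` and ``between_sd`` place the process on a
    0-100 slider scale by default (grand mean 50, within-person residual
    SD 18, between-person mean SD 12); estimation is scale-invariant under
    standardisation, so these matter only when emulating raw sliders.
    """
    if m < 2:
        raise GenerationError("need at least 2 nodes")
    if not 0 < edge_density <= 1:
        raise GenerationError(
            "edge_density must be in (0, 1]; for a null truth use empty_truth()"
        )
    if not 0 < weight_low <= weight_high:
        raise GenerationError("need 0 < weight_low <= weight_high")
    rng = np.random.default_rng(seed)

    b = np.zeros((m, m))
    off = ~np.eye(m, dtype=bool)
    keep = rng.random((m, m)) < edge_density
    signs = rng.choice([-1.0, 1.0], (m, m))
    mags = rng.uniform(weight_low, weight_high, (m, m))
    b[off] = (keep * signs * mags)[off]
    np.fill_diagonal(b, rng.uniform(weight_low, weight_high, m))
    radius = _spectral_radius(b)
    if radius > MAX_SPECTRAL_RADIUS:
        b *= MAX_SPECTRAL_RADIUS / radius

    theta = _sparse_precision(m, edge_density, weight_low, weight_high, rng)
    omega_b = _sparse_precision(m, edge_density, weight_low, weight_high, rng)
    sigma_b = np.linalg.inv(omega_b)
    # scale so that the average person-mean variance is between_sd^2
    sigma_b *= between_sd**2 / np.mean(np.diag(sigma_b))

    names = item_names or [f"V{i + 1:02d}" for i in range(m)]
    if len(names) != m:
        raise GenerationError(f"item_names must have length {m}")
    mu_vec = np.full(m, float(mu)) if np.isscalar(mu) else np.asarray(mu, dtype=float)
    return SimulationTruth(
        item_names=names,
        B=b,
        Theta=theta,
        Sigma_between=sigma_b,
        mu=mu_vec,
        noise_scale=noise_scale,
        seed=seed,
    )


def empty_truth(
    m: int,
    item_names: list[str] | None = None,
    mu: np.ndarray | float = 50.0,
    noise_scale: float = 18.0,
    between_sd: float = 12.0,
) -> SimulationTruth:
    """Null truth: B = 0, independent residuals, independent person means.

    All three true networks are empty — the reference point for
    false-positive-rate studies.
    """
    names = item_names or [f"V{i + 1:02d}" for i in range(m)]
    mu_vec = np.full(m, float(mu)) if np.isscalar(mu) else np.asarray(mu, dtype=float)
    return SimulationTruth(
        item_names=names,
        B=np.zeros((m, m)),
        Theta=np.eye(m),
        Sigma_between=between_sd**2 * np.eye(m),
        mu=mu_vec,
        noise_scale=noise_scale,
        seed=None,
    )


def _default_items(truth: SimulationTruth) -> list[ItemSpec]:
    study = stress_affect_eating_items()
    if truth.item_names == [it.name for it in study]:
        return study
    return [ItemSpec(n, n, "other", -np.inf, np.inf) for n in truth.item_names]


def simulate_dataset(
    truth: SimulationTruth,
    config: SimulationConfig,
    items: list[ItemSpec] | None = None,
) -> EMADataset:
    """Simulate one EMA dataset from a known truth.

    Per person: draw mu_i ~ MVN(mu, Sigma_between), run ``config.burn_in``
    unrecorded VAR steps from mu_i, then record schedule.n_occasions
    occasions in temporal order (day boundaries are crossed by the
    process).  Whole occasions are then deleted with probability
    ``missing_beep_rate``; on surviving occasions each skippable item is
    additionally deleted with probability ``eating_item_missing_rate``.
    With ``clip_to_range`` the values are clipped to the item ranges and
    the clipped fraction recorded in ``attrs['clipped_fraction']``.

    Identical (truth, config) including seed give bit-identical datasets.
    """
    if items is None:
        items = _default_items(truth)
    if [it.name for it in items] != truth.item_names:
        raise ValueError("items must match truth.item_names in order")
    if not config.clip_to_range:
        # the Gaussian process is unbounded; without clipping, slider
        # bounds would spuriously fail validation
        items = [replace(it, range_min=-np.inf, range_max=np.inf) for it in items]
    m = truth.m
    rng = np.random.default_rng(config.seed)
    n_occ = config.schedule.n_occasions

    resid_cov = truth.noise_scale**2 * np.linalg.inv(truth.Theta)
    chol_resid = np.linalg.cholesky(resid_cov)
    chol_between = np.linalg.cholesky(truth.Sigma_between)

    frames = np.empty((config.n_persons, n_occ, m))
    for i in range(config.n_persons):
        mu_i = truth.mu + chol_between @ rng.standard_normal(m)
        y = mu_i.copy()
        eps = rng.standard_normal((config.burn_in + n_occ, m)) @ chol_resid.T
        for t in range(config.burn_in):
            y = mu_i + truth.B @ (y - mu_i) + eps[t]
        for t in range(n_occ):
            y = mu_i + truth.B @ (y - mu_i) + eps[config.burn_in + t]
            frames[i, t] = y

    clipped = 0.0
    if config.clip_to_range:
        lo = np.array([it.range_min for it in items])
        hi = np.array([it.range_max for it in items])
        before = frames.copy()
        frames = np.clip(frames, lo, hi)
        clipped = float(np.mean(frames != before))

    # beep-level MCAR missingness, then extra missingness on skippable items
    miss_beep = rng.random((config.n_persons, n_occ)) < config.missing_beep_rate
    frames[miss_beep] = np.nan
    for j, it in enumerate(items):
        if it.skippable and config.eating_item_missing_rate > 0:
            miss_item = rng.random((config.n_persons, n_occ)) < config.eating_item_missing_rate
            frames[:, :, j] = np.where(miss_item, np.nan, frames[:, :, j])

    persons = [f"p{i + 1:03d}" for i in range(config.n_persons)]
    index = pd.MultiIndex.from_product(
        [persons, range(1, config.schedule.n_days + 1), range(1, config.schedule.beeps_per_day + 1)],
        names=["person_id", "day", "beep"],
    )
    data = pd.DataFrame(
        frames.reshape(config.n_persons * n_occ, m), index=index, columns=truth.item_names
    )
    return EMADataset(
        data,
        schedule=config.schedule,
        items=list(items),
        attrs={
            "seed": config.seed,
            "truth": truth,
            "config": config.to_dict(),
            "clipped_fraction": clipped,
        },
    )
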