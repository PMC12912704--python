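"""Noise schedule, forward diffusion, masked composition, reverse sampling.

The model is a standard variance-preserving DDPM.  With per-step retention
factors ``alpha_t`` and cumulative products ``gamma_t = prod_{i<=t} alpha_i``,

    forward:  x_t = sqrt(gamma_t) * x0 + sqrt(1 - gamma_t) * eps,  eps ~ N(0, I)
    reverse:  x_{t-1} = (x_t - (1 - alpha_t)/sqrt(1 - gamma_t) * eps_hat)
                        / sqrt(alpha_t)  +  sqrt(1 - alpha_t) * eps_t

with fresh noise ``eps_t`` for t > 1 and ``eps_t = 0`` at the final step.
During training the noisy state is spliced with the clean conditional via a
shared-gene mask so only unique-gene entries carry diffusion noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import ExpressionMatrix, GeneMask


@dataclass
class NoiseSchedule:
    """Per-step retention ``alpha`` and cumulative retention ``gamma``."""

    T: int
    alpha: np.ndarray  # length T, alpha[t-1] is alpha_t
    gamma: np.ndarray  # length T, gamma[t-1] is gamma_t

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        if self.T < 1 or len(self.alpha) != self.T or len(self.gamma) != self.T:
            raise ValueError("schedule length mismatch")
        if np.any(self.alpha <= 0) or np.any(self.alpha >= 1):
            raise ValueError("alpha_t must lie strictly in (0, 1)")
        if np.any(np.diff(self.gamma) >= 0):
            raise ValueError("gamma must be strictly decreasing")

    def a(self, t: int) -> float:
        self._check_t(t)
        return float(self.alpha[t - 1])

    def g(self, t: int) -> float:
        self._check_t(t)
        return float(self.gamma[t - 1])

    def _check_t(self, t: int) -> None:
        if not 1 <= t <= self.T:
            raise ValueError(f"timestep {t} outside 1..{self.T}")


def build_cosine_schedule(T: int, offset: float = 0.008) -> NoiseSchedule:
    """Cosine cumulative-retention schedule.

    gamma_t = f(t)/f(0) with f(u) = cos^2(((u/T + offset)/(1 + offset)) * pi/2);
    alpha_t = gamma_t / gamma_{t-1}, clipped into (1e-6, 0.9999) with gamma
    recomputed from the clipped alphas so the product identity holds exactly.
    """
    if T < 1:
        raise ValueError("T must be >= 1")

    def f(u: float) -> float:
        return np.cos(((u / T + offset) / (1.0 + offset)) * np.pi / 2.0) ** 2

    f0 = f(0.0)
    gamma_raw = np.array([f(t) / f0 for t in range(1, T + 1)])
    prev = np.concatenate([[1.0], gamma_raw[:-1]])
    alpha = np.clip(gamma_raw / prev, 1e-6, 0.9999)
    gamma = np.cumprod(alpha)
    return NoiseSchedule(T=T, alpha=alpha, gamma=gamma)


def forward_diffuse(
    x0: np.ndarray, t: int, eps: np.ndarray, s: NoiseSchedule
) -> np.ndarray:
    """x_t = sqrt(gamma_t) x0 + sqrt(1 - gamma_t) eps."""
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if x0.shape != eps.shape:
        raise ValueError(f"shape mismatch: x0 {x0.shape} vs eps {eps.shape}")
    g = s.g(t)
    return np.sqrt(g) * x0 + np.sqrt(1.0 - g) * eps


def compose_masked_input(
    x0_like: np.ndarray, xt: np.ndarray, m: GeneMask | np.ndarray
) -> np.ndarray:
    """Splice: shared-gene entries from `x0_like`, unique-gene entries from `xt`."""
    mask = m.m if isinstance(m, GeneMask) else np.asarray(m, dtype=np.float64)
    x0_like = np.asarray(x0_like, dtype=np.float64)
    xt = np.asarray(xt, dtype=np.float64)
    if not (x0_like.shape == xt.shape == mask.shape):
        raise ValueError(
            f"shape mismatch: {x0_like.shape}, {xt.shape}, {mask.shape}"
        )
    return x0_like * mask + xt * (1.0 - mask)


def reverse_step(
    xt: np.ndarray,
    eps_hat: np.ndarray,
    t: int,
    s: NoiseSchedule,
    eps_t: np.ndarray | float = 0.0,
) -> np.ndarray:
    """One reverse-denoising update from x_t to x_{t-1}.

    `eps_t` must be fresh standard-normal noise for t > 1 and zero at t = 1.
    """
    xt = np.asarray(xt, dtype=np.float64)
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    if xt.shape != eps_hat.shape:
        raise ValueError(f"shape mismatch: xt {xt.shape} vs eps_hat {eps_hat.shape}")
    a, g = s.a(t), s.g(t)
    mean = (xt - (1.0 - a) / np.sqrt(1.0 - g) * eps_hat) / np.sqrt(a)
    return mean + np.sqrt(1.0 - a) * np.asarray(eps_t, dtype=np.float64)


def perturb_reference(
    x0: ExpressionMatrix | np.ndarray, sd: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Inject elementwise Gaussian noise into the reference before diffusion.

    The perturbation diversifies training inputs and blurs modality-specific
    level differences so the model emphasizes gene-gene relationships over
    absolute values.  ``sd = 0`` returns the input unchanged.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    vals = x0.values if isinstance(x0, ExpressionMatrix) else np.asarray(x0, float)
    if sd == 0:
        return vals.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return vals + rng.normal(0.0, sd, size=vals.shape)
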