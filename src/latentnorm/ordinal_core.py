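"""Latent-variable <-> ordinal-response machinery.

A Likert response arises by partitioning a continuous latent variable at
ordered thresholds: response ``k`` is observed when the latent value falls in
``(tau_{k-1}, tau_k]`` with implicit ``tau_0 = -inf`` and ``tau_K = +inf``.
This module provides the link functions, a registry of five stylised
response patterns (threshold configurations), recoding of latent values to
responses, and closed-form response probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "LinkFunction",
    "ThresholdSet",
    "get_link",
    "pattern_names",
    "make_pattern",
    "recode_latent",
    "response_probs",
    "sample_responses",
    "export_pattern_registry",
    "PROB_FLOOR",
    "CDF_CEIL",
]

# Clipping bounds for cdf values entering likelihoods: avoids exactly-zero
# cells while leaving response_probs itself exact.
PROB_FLOOR = 1e-300
CDF_CEIL = 1.0 - 1e-16


@dataclass(frozen=True)
class LinkFunction:
    """A cumulative link: monotone cdf mapping the latent scale to (0, 1)."""

    name: str
    cdf: Callable[[np.ndarray], np.ndarray]
    density: Callable[[np.ndarray], np.ndarray]
    ppf: Callable[[np.ndarray], np.ndarray]


_LINKS = {
    "probit": LinkFunction("probit", stats.norm.cdf, stats.norm.pdf, stats.norm.ppf),
    "logit": LinkFunction(
        "logit", stats.logistic.cdf, stats.logistic.pdf, stats.logistic.ppf
    ),
}


def get_link(name: str | LinkFunction) -> LinkFunction:
    """Resolve a link by name (``probit`` or ``logit``)."""
    if isinstance(name, LinkFunction):
        return name
    try:
        return _LINKS[name]
    except KeyError:
        raise ValueError(
            f"unknown link {name!r}; available: {sorted(_LINKS)}"
        ) from None


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered latent cut-points defining a response pattern.

    ``K`` response levels require ``K - 1`` strictly increasing thresholds;
    the outermost cut-points at +-inf are implicit.
    """

    n_levels: int
    tau: np.ndarray
    pattern_name: str | None = field(default=None)

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        object.__setattr__(self, "tau", tau)
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if tau.ndim != 1 or tau.size != self.n_levels - 1:
            raise ValueError(
                f"expected {self.n_levels - 1} thresholds, got {tau.size}"
            )
        if not np.all(np.isfinite(tau)):
            raise ValueError("thresholds must be finite")
        if not np.all(np.diff(tau) > 0):
            raise ValueError("thresholds must be strictly increasing")


# Fixed default registry for K=5.  The constants are constrained to
# reproduce the worked recoding example: a latent value of 2.5 maps to
# responses 4, 3, 5, 5, 4 under equidistant, left-biased, right-biased,
# edge-biased and centre-biased patterns respectively.
_PATTERNS_K5: dict[str, tuple[float, ...]] = {
    "equidistant": (-3.0, -1.0, 1.0, 3.0),
    "left-biased": (-1.0, 1.0, 3.0, 5.0),
    "right-biased": (-5.0, -3.0, -1.0, 1.0),
    "edge-biased": (-1.0, -0.35, 0.35, 1.0),
    "centre-biased": (-4.0, -1.5, 1.5, 4.0),
}


def pattern_names() -> tuple[str, ...]:
    """Names of the registered response patterns, in registry order."""
    return tuple(_PATTERNS_K5)


def make_pattern(name: str, n_levels: int = 5) -> ThresholdSet:
    """Build the default :class:`ThresholdSet` for a named response pattern.

    Only ``n_levels = 5`` is registered; other level counts raise.
    """
    if name not in _PATTERNS_K5:
        raise ValueError(
            f"unknown pattern {name!r}; available: {sorted(_PATTERNS_K5)}"
        )
    if n_levels != 5:
        raise ValueError(
            f"pattern registry only defines n_levels=5 (got {n_levels})"
        )
    return ThresholdSet(n_levels, np.array(_PATTERNS_K5[name]), pattern_name=name)


def recode_latent(value, thresholds: ThresholdSet):
    """Map latent value(s) to ordinal response(s) in ``1..K``.

    A value in ``(tau_{k-1}, tau_k]`` maps to ``k``: the response is
    ``1 + #{k : value > tau_k}``, so a value exactly on a threshold falls in
    the lower region.
    """
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("latent values must be finite")
    resp = 1 + np.searchsorted(thresholds.tau, arr, side="left")
    if np.isscalar(value) or arr.ndim == 0:
        return int(resp)
    return resp.astype(np.int64)


def response_probs(
    mu: float,
    sd: float,
    thresholds: ThresholdSet,
    link: str | LinkFunction = "probit",
) -> np.ndarray:
    """Probability of each response level for a latent location/scale.

    ``p_k = cdf((tau_k - mu)/sd) - cdf((tau_{k-1} - mu)/sd)`` with the
    implicit outer cut-points contributing 0 and 1 exactly.
    """
    if not sd > 0:
        raise ValueError(f"sd must be > 0 (got {sd})")
    lk = get_link(link)
    z = (thresholds.tau - mu) / sd
    cum = np.concatenate(([0.0], lk.cdf(z), [1.0]))
    p = np.diff(cum)
    return np.clip(p, 0.0, 1.0)


def sample_responses(
    mu: float,
    sd: float,
    n: int,
    thresholds: ThresholdSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` latent values from Normal(mu, sd) and recode them."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    latent = mu + sd * rng.standard_normal(n)
    return recode_latent(latent, thresholds)


def export_pattern_registry(path) -> None:
    """Write the pattern registry as a small delimited-text table."""
    import pandas as pd

    rows = [
        {"pattern": name, "n_levels": 5, "tau": " ".join(map(str, tau))}
        for name, tau in _PATTERNS_K5.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
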