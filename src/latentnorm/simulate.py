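"""Trial-level rating simulators.

Generative models:

* items only: ``L_i = mu_i + e_i`` with ``mu_i ~ item_re_dist`` and
  ``e_i ~ residual_dist`` (25 draws per item by default);
* crossed: ``L_ij ~ Normal(mu_i + mu_j, sigma_ij)`` with
  ``sigma_ij = 1 / exp(disc_i + disc_j)``, which with zero discrimination
  variance reduces to ``L_ij = mu_i + mu_j + e_ij``;
* non-normal variants swapping either the per-trial residual or the item
  random-effect distribution for a logistic, uniform, bimodal or
  half-normal alternative.

Latent values are recoded to ordinal responses with a named threshold
pattern, and the ground truth is carried along in extra columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from latentnorm.ordinal_core import ThresholdSet, make_pattern, recode_latent

__all__ = [
    "SimulationDesign",
    "allocate",
    "simulate_items_only",
    "simulate_crossed",
    "simulate_nonnormal",
    "draw_distribution",
    "DISTRIBUTIONS",
]

# Fixed parameterisations of the non-normal alternatives: logistic(0, 1),
# uniform(-2, 2), an equal mixture of N(-1.5, .75) and N(1.5, .75), and the
# positive half of N(0, 1) (|Z|, not recentred).
DISTRIBUTIONS = ("normal", "logistic", "uniform", "bimodal", "halfnormal")


def draw_distribution(name: str, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` values from one of the named fixed distributions."""
    if name == "normal":
        return rng.standard_normal(size)
    if name == "logistic":
        return rng.logistic(0.0, 1.0, size)
    if name == "uniform":
        return rng.uniform(-2.0, 2.0, size)
    if name == "bimodal":
        sign = np.where(rng.random(size) < 0.5, -1.0, 1.0)
        return sign * 1.5 + 0.75 * rng.standard_normal(size)
    if name == "halfnormal":
        return np.abs(rng.standard_normal(size))
    raise ValueError(f"unknown distribution {name!r}; available: {DISTRIBUTIONS}")


@dataclass
class SimulationDesign:
    """Design of one simulated norming dataset."""

    n_items: int = 100
    ratings_per_item: int = 25
    n_participants: int | None = None
    items_per_participant: int | None = None
    sd_mu_item: float = 1.0
    sd_mu_participant: float = 1.0
    sd_disc_item: float = 0.0
    sd_disc_participant: float = 0.0
    sd_residual: float = 1.0
    residual_dist: str = "normal"
    item_re_dist: str = "normal"
    seed: int | None = None
    pattern: str | ThresholdSet = "equidistant"

    def __post_init__(self) -> None:
        for name in ("sd_mu_item", "sd_mu_participant", "sd_disc_item",
                     "sd_disc_participant", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_items < 1 or self.ratings_per_item < 1:
            raise ValueError("n_items and ratings_per_item must be >= 1")
        if (self.n_participants is None) != (self.items_per_participant is None):
            raise ValueError(
                "n_participants and items_per_participant must be given together"
            )
        if self.n_participants is not None:
            if (self.n_participants * self.items_per_participant
                    != self.n_items * self.ratings_per_item):
                raise ValueError(
                    "n_participants * items_per_participant must equal "
                    "n_items * ratings_per_item"
                )

    def resolve_pattern(self) -> ThresholdSet:
        if isinstance(self.pattern, ThresholdSet):
            return self.pattern
        return make_pattern(self.pattern)


def _item_ids(n: int) -> np.ndarray:
    width = max(3, len(str(n)))
    return np.array([f"item_{i + 1:0{width}d}" for i in range(n)])


def _participant_ids(n: int) -> np.ndarray:
    width = max(3, len(str(n)))
    return np.array([f"part_{j + 1:0{width}d}" for j in range(n)])


def _rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    """Deterministic independent sub-streams from one seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def allocate(
    n_items: int,
    n_participants: int,
    items_per_participant: int,
    rng: np.random.Generator,
    max_retries: int = 50,
) -> pd.DataFrame:
    """Pseudo-randomly assign participants to items in a balanced design.

    Every participant rates ``items_per_participant`` distinct items and
    every item is rated by exactly
    ``n_participants * items_per_participant / n_items`` participants.
    Random permutations of the item list are concatenated and chunked into
    participant blocks; blocks containing a duplicate item are repaired by
    swapping entries with other blocks (bounded random retries first, then a
    deterministic sweep).
    """
    total = n_participants * items_per_participant
    if total % n_items != 0:
        raise ValueError(
            "n_participants * items_per_participant must be divisible by n_items"
        )
    if items_per_participant > n_items:
        raise ValueError("items_per_participant cannot exceed n_items")
    n_copies = total // n_items

    pool = np.concatenate(
        [rng.permutation(n_items) for _ in range(n_copies)]
    )
    blocks = pool.reshape(n_participants, items_per_participant)

    def dup_rows(b: np.ndarray) -> np.ndarray:
        has_dup = np.array(
            [len(np.unique(row)) != row.size for row in b]
        )
        return np.flatnonzero(has_dup)

    for _ in range(max_retries):
        bad = dup_rows(blocks)
        if bad.size == 0:
            break
        # reshuffle the union of the offending blocks among themselves
        flat = blocks[bad].ravel()
        rng.shuffle(flat)
        blocks[bad] = flat.reshape(bad.size, items_per_participant)
    # deterministic repair: swap a duplicated entry with a compatible entry
    # from another block
    bad = dup_rows(blocks)
    for r in bad:
        row = blocks[r]
        seen: set[int] = set()
        for c in range(row.size):
            v = row[c]
            if v not in seen:
                seen.add(v)
                continue
            fixed = False
            for r2 in range(n_participants):
                if r2 == r:
                    continue
                for c2 in range(items_per_participant):
                    w = blocks[r2, c2]
                    if w not in seen and v not in blocks[r2]:
                        blocks[r, c], blocks[r2, c2] = w, v
                        seen.add(w)
                        fixed = True
                        break
                if fixed:
                    break
            if not fixed:
                raise RuntimeError("allocation repair failed; design infeasible")
    if dup_rows(blocks).size:
        raise RuntimeError("allocation repair failed; design infeasible")

    items = _item_ids(n_items)
    parts = _participant_ids(n_participants)
    part_idx = np.repeat(np.arange(n_participants), items_per_participant)
    item_idx = blocks.ravel()
    return pd.DataFrame(
        {
            "participant_id": parts[part_idx],
            "item_id": items[item_idx],
            "_item_idx": item_idx,
            "_part_idx": part_idx,
        }
    )


def simulate_items_only(
    design: SimulationDesign,
    pattern: str | ThresholdSet | None = None,
) -> pd.DataFrame:
    """Items-only generator: ``ratings_per_item`` latent draws per item."""
    if design.n_participants is not None:
        raise ValueError("items-only design must not declare participants")
    if design.sd_disc_item or design.sd_disc_participant:
        raise ValueError("items-only design does not support disc effects")
    thr = (design.resolve_pattern() if pattern is None
           else pattern if isinstance(pattern, ThresholdSet)
           else make_pattern(pattern))
    rng_re, rng_resid = _rngs(design.seed, 2)

    n, r = design.n_items, design.ratings_per_item
    mu_i = design.sd_mu_item * draw_distribution(design.item_re_dist, n, rng_re)
    resid = design.sd_residual * draw_distribution(design.residual_dist, n * r, rng_resid)
    latent = np.repeat(mu_i, r) + resid
    df = pd.DataFrame(
        {
            "item_id": np.repeat(_item_ids(n), r),
            "response": recode_latent(latent, thr),
            "latent": latent,
            "mu_item": np.repeat(mu_i, r),
        }
    )
    df.attrs["pattern"] = thr.pattern_name
    df.attrs["n_levels"] = thr.n_levels
    return df


def simulate_crossed(
    design: SimulationDesign,
    pattern: str | ThresholdSet | None = None,
) -> pd.DataFrame:
    """Crossed item x participant generator with optional disc effects.

    ``L_ij = mu_i + mu_j + sigma_ij * e_ij`` with
    ``sigma_ij = 1/exp(disc_i + disc_j)`` and ``e_ij ~ residual_dist``
    (standard normal by default, giving ``L_ij ~ N(mu_i + mu_j, sigma_ij)``).
    """
    if design.n_participants is None:
        raise ValueError("crossed design requires participants")
    thr = (design.resolve_pattern() if pattern is None
           else pattern if isinstance(pattern, ThresholdSet)
           else make_pattern(pattern))
    rng_alloc, rng_item, rng_part, rng_resid = _rngs(design.seed, 4)

    alloc = allocate(
        design.n_items, design.n_participants, design.items_per_participant,
        rng_alloc,
    )
    n_i, n_j = design.n_items, design.n_participants
    mu_i = design.sd_mu_item * draw_distribution(design.item_re_dist, n_i, rng_item)
    disc_i = design.sd_disc_item * rng_item.standard_normal(n_i)
    mu_j = design.sd_mu_participant * rng_part.standard_normal(n_j)
    disc_j = design.sd_disc_participant * rng_part.standard_normal(n_j)

    ii = alloc["_item_idx"].to_numpy()
    jj = alloc["_part_idx"].to_numpy()
    sigma = 1.0 / np.exp(disc_i[ii] + disc_j[jj])
    resid = design.sd_residual * draw_distribution(
        design.residual_dist, len(alloc), rng_resid
    )
    latent = mu_i[ii] + mu_j[jj] + sigma * resid

    df = pd.DataFrame(
        {
            "participant_id": alloc["participant_id"].to_numpy(),
            "item_id": alloc["item_id"].to_numpy(),
            "response": recode_latent(latent, thr),
            "latent": latent,
            "mu_item": mu_i[ii],
            "mu_participant": mu_j[jj],
            "disc_item": disc_i[ii],
            "disc_participant": disc_j[jj],
            "latent_sd": sigma,
        }
    )
    df.attrs["pattern"] = thr.pattern_name
    df.attrs["n_levels"] = thr.n_levels
    return df


def simulate_nonnormal(
    design: SimulationDesign,
    target: str,
    dist: str,
    pattern: str | ThresholdSet | None = None,
) -> pd.DataFrame:
    """Crossed generator with one non-normal component.

    ``target='latent_residual'`` swaps the per-trial residual distribution;
    ``target='item_re'`` swaps the item random-effect distribution.  With
    ``dist='normal'`` the output is identical to :func:`simulate_crossed`
    under the same seed.
    """
    if dist not in DISTRIBUTIONS:
        raise ValueError(f"unknown distribution {dist!r}; available: {DISTRIBUTIONS}")
    if target not in ("latent_residual", "item_re"):
        raise ValueError("target must be 'latent_residual' or 'item_re'")
    import dataclasses

    if target == "latent_residual":
        design = dataclasses.replace(design, residual_dist=dist)
    else:
        design = dataclasses.replace(design, item_re_dist=dist)
    return simulate_crossed(design, pattern)
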