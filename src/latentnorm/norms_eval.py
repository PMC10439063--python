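"""Baseline norming methods, norm tables and the evaluation procedures.

Norm estimators share a common table layout (one row per item, fixed column
order) so that raw means, within-participant z-scores, Gaussian LMM
conditional modes and CLMM latent means can be compared side by side.  The
evaluation half implements recovery-error summaries (raw and scaled),
split-half consistency and an orchestrator for the simulation studies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from latentnorm.clmm_ml import CLMMSpec, fit_clmm, ranef
from latentnorm.ordinal_core import ThresholdSet, response_probs
from latentnorm.simulate import (
    SimulationDesign,
    simulate_crossed,
    simulate_items_only,
    simulate_nonnormal,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NORM_COLUMNS",
    "EvaluationReport",
    "raw_norms",
    "zscore_norms",
    "lmm_norms",
    "clmm_ml_norms",
    "gaussian_blups",
    "predict_item_probs",
    "recovery_error",
    "split_half_consistency",
    "run_experiment",
    "estimate_column",
]

NORM_COLUMNS = [
    "item_id", "n", "raw_mean", "raw_sd",
    "latent_mean", "latent_mean_lo", "latent_mean_hi",
    "latent_sd", "latent_sd_lo", "latent_sd_hi", "method",
]


def _empty_norms(index: pd.Index) -> pd.DataFrame:
    df = pd.DataFrame({"item_id": index.to_numpy()})
    for c in NORM_COLUMNS[1:-1]:
        df[c] = np.nan
    df["method"] = ""
    return df


def _raw_stats(trials: pd.DataFrame) -> pd.DataFrame:
    grp = trials.groupby("item_id")["response"]
    out = grp.agg(n="size", raw_mean="mean")
    out["raw_sd"] = grp.std(ddof=1)
    return out


def raw_norms(trials: pd.DataFrame) -> pd.DataFrame:
    """Traditional per-item mean, sample SD (n-1) and rating count."""
    if not len(trials):
        raise ValueError("empty trial table")
    stats = _raw_stats(trials)
    out = _empty_norms(stats.index)
    out["n"] = stats["n"].to_numpy()
    out["raw_mean"] = stats["raw_mean"].to_numpy()
    out["raw_sd"] = stats["raw_sd"].to_numpy()
    out["method"] = "raw"
    return out[NORM_COLUMNS].sort_values("item_id", ignore_index=True)


def zscore_norms(trials: pd.DataFrame) -> pd.DataFrame:
    """Within-participant z-scores averaged per item.

    Participants with zero response variance carry no ordinal information
    after standardisation and are excluded (logged).
    """
    if "participant_id" not in trials.columns:
        raise ValueError("z-score norms require participant ids")
    df = trials[["participant_id", "item_id", "response"]].copy()
    grp = df.groupby("participant_id")["response"]
    sd = grp.transform(lambda s: s.std(ddof=1))
    mean = grp.transform("mean")
    bad = ~(sd > 0)
    n_bad = df.loc[bad, "participant_id"].nunique()
    if n_bad:
        logger.warning(
            "excluding %d zero-variance participants from z-score norms", n_bad
        )
        df = df[~bad]
        sd, mean = sd[~bad], mean[~bad]
    if not len(df):
        raise ValueError("no participants with response variance")
    df = df.assign(z=(df["response"] - mean) / sd)
    z_means = df.groupby("item_id")["z"].mean()

    stats = _raw_stats(trials)
    out = _empty_norms(stats.index)
    out["n"] = stats["n"].to_numpy()
    out["raw_mean"] = stats["raw_mean"].to_numpy()
    out["raw_sd"] = stats["raw_sd"].to_numpy()
    aligned = z_means.reindex(stats.index)
    out["latent_mean"] = aligned.to_numpy()
    out["zscored_mean"] = aligned.to_numpy()
    out["method"] = "zscore"
    return out[NORM_COLUMNS + ["zscored_mean"]].sort_values(
        "item_id", ignore_index=True
    )


# ---------------------------------------------------------------------------
# Gaussian crossed LMM


def gaussian_blups(
    y: np.ndarray,
    item_idx: np.ndarray,
    part_idx: np.ndarray,
    n_items: int,
    n_parts: int,
    sd_item: float,
    sd_part: float,
    sd_resid: float,
    grand_mean: float | None = None,
):
    """BLUPs of crossed random intercepts at fixed variance components.

    Returns (item BLUPs, participant BLUPs, grand mean, conditional variances).
    Uses the q x q identity ``D Z' V^-1 = (D^-1 + Z'Z / s2)^-1 Z' / s2``.
    """
    n = y.size
    q = n_items + n_parts
    s2 = sd_resid**2
    Z_cols = np.concatenate([item_idx, n_items + part_idx])
    rows = np.tile(np.arange(n), 2)
    from scipy import sparse

    Z = sparse.coo_matrix(
        (np.ones(2 * n), (rows, Z_cols)), shape=(n, q)
    ).tocsr()
    ZtZ = (Z.T @ Z).toarray()
    d_inv = np.concatenate(
        [
            np.full(n_items, 1.0 / max(sd_item, 1e-8) ** 2),
            np.full(n_parts, 1.0 / max(sd_part, 1e-8) ** 2),
        ]
    )
    A = ZtZ / s2 + np.diag(d_inv)
    A_inv = np.linalg.inv(A)

    def vinv_dot(v):
        Ztv = Z.T @ v
        return (v - Z @ (A_inv @ (Ztv / s2))) / s2

    ones = np.ones(n)
    if grand_mean is None:
        grand_mean = float(ones @ vinv_dot(y)) / float(ones @ vinv_dot(ones))
    r = y - grand_mean
    b = A_inv @ (Z.T @ r) / s2
    cond_var = np.clip(np.diag(A_inv), 0.0, None)
    return b[:n_items], b[n_items:], grand_mean, cond_var


def _gaussian_lmm_ml(y, item_idx, part_idx, n_items, n_parts):
    """ML variance components for the crossed Gaussian random-intercept model."""
    n = y.size
    from scipy import sparse

    Z_cols = np.concatenate([item_idx, n_items + part_idx])
    rows = np.tile(np.arange(n), 2)
    Z = sparse.coo_matrix(
        (np.ones(2 * n), (rows, Z_cols)), shape=(n, n_items + n_parts)
    ).tocsr()
    ZtZ = (Z.T @ Z).toarray()
    Zty = Z.T @ y
    Zt1 = Z.T @ np.ones(n)
    yty = float(y @ y)
    ysum = float(y.sum())

    def negloglik(theta):
        sa, sb, se = np.exp(theta)
        s2 = se**2
        d = np.concatenate(
            [np.full(n_items, sa**2), np.full(n_parts, sb**2)]
        )
        A = ZtZ / s2 + np.diag(1.0 / d)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12
        logdet_V = n * math.log(s2) + logdet_A + float(np.log(d).sum())
        A_inv = np.linalg.inv(A)

        def quad(u_t_z_a, u_t_z_b, uu):
            # u' V^-1 v style quadratic forms via the Woodbury identity
            return (uu - float(u_t_z_a @ (A_inv @ u_t_z_b)) / s2) / s2

        q_yy = quad(Zty, Zty, yty)
        q_y1 = quad(Zty, Zt1, ysum)
        q_11 = quad(Zt1, Zt1, float(n))
        m = q_y1 / q_11
        rVr = q_yy - 2 * m * q_y1 + m * m * q_11
        return 0.5 * (n * math.log(2 * math.pi) + logdet_V + rVr)

    res = optimize.minimize(
        negloglik,
        np.log([0.7, 0.7, 0.7]),
        method="L-BFGS-B",
        bounds=[(math.log(1e-6), 4.0)] * 3,
    )
    sa, sb, se = np.exp(res.x)
    return sa, sb, se, bool(res.success), -float(res.fun)


def lmm_norms(trials: pd.DataFrame) -> pd.DataFrame:
    """Gaussian LMM norms: item conditional modes on the raw 1..K scale.

    Fits ``response ~ 1 + (1|item) + (1|participant)`` with an identity link
    by maximum likelihood (exact marginal Gaussian likelihood), then reports
    item BLUPs as ``latent_mean`` (grand mean in ``df.attrs``).
    """
    if "participant_id" not in trials.columns:
        raise ValueError("LMM norms require participant ids")
    item_codes, item_levels = pd.factorize(trials["item_id"], sort=True)
    part_codes, part_levels = pd.factorize(trials["participant_id"], sort=True)
    y = trials["response"].to_numpy(dtype=float)
    sa, sb, se, ok, ll = _gaussian_lmm_ml(
        y, item_codes, part_codes, len(item_levels), len(part_levels)
    )
    if not ok:
        logger.warning("Gaussian LMM variance-component optimisation flagged "
                       "non-convergence")
    b_item, _, gm, cond_var = gaussian_blups(
        y, item_codes, part_codes, len(item_levels), len(part_levels),
        sa, sb, se,
    )
    stats = _raw_stats(trials)
    out = _empty_norms(pd.Index(item_levels))
    aligned = stats.reindex(item_levels)
    out["n"] = aligned["n"].to_numpy()
    out["raw_mean"] = aligned["raw_mean"].to_numpy()
    out["raw_sd"] = aligned["raw_sd"].to_numpy()
    out["latent_mean"] = b_item
    sd_item = np.sqrt(cond_var[: len(item_levels)])
    out["latent_mean_lo"] = b_item - sd_item
    out["latent_mean_hi"] = b_item + sd_item
    out["method"] = "lmm"
    out = out[NORM_COLUMNS].sort_values("item_id", ignore_index=True)
    out.attrs["grand_mean"] = gm
    out.attrs["sd_item"] = sa
    out.attrs["sd_participant"] = sb
    out.attrs["sd_resid"] = se
    out.attrs["loglik"] = ll
    return out


def clmm_ml_norms(
    trials: pd.DataFrame,
    n_levels: int,
    factors: tuple[str, ...] | None = None,
    link: str = "probit",
) -> pd.DataFrame:
    """Norms from the ML CLMM: item conditional modes as latent means."""
    if factors is None:
        factors = (
            ("item", "participant")
            if "participant_id" in trials.columns
            else ("item",)
        )
    fit = fit_clmm(trials, CLMMSpec(n_levels=n_levels, factors=factors, link=link))
    re = ranef(fit, "item").set_index("level")
    stats = _raw_stats(trials)
    out = _empty_norms(stats.index)
    out["n"] = stats["n"].to_numpy()
    out["raw_mean"] = stats["raw_mean"].to_numpy()
    out["raw_sd"] = stats["raw_sd"].to_numpy()
    aligned = re.reindex(stats.index)
    out["latent_mean"] = aligned["mode"].to_numpy()
    out["latent_mean_lo"] = (aligned["mode"] - aligned["cond_sd"]).to_numpy()
    out["latent_mean_hi"] = (aligned["mode"] + aligned["cond_sd"]).to_numpy()
    out["method"] = "clmm_ml"
    out = out[NORM_COLUMNS].sort_values("item_id", ignore_index=True)
    out.attrs["fit"] = fit
    return out


def estimate_column(norms: pd.DataFrame) -> pd.Series:
    """The per-item point estimate a method ranks and compares items by."""
    method = norms["method"].iloc[0]
    col = "raw_mean" if method == "raw" else "latent_mean"
    return norms.set_index("item_id")[col]


def predict_item_probs(
    norms: pd.DataFrame,
    thresholds: ThresholdSet,
    item_id: str,
    link: str = "probit",
) -> np.ndarray:
    """Predict response probabilities for one item from its latent norms."""
    row = norms.loc[norms["item_id"] == item_id]
    if not len(row):
        raise ValueError(f"unknown item {item_id!r}")
    mu = float(row["latent_mean"].iloc[0])
    if not np.isfinite(mu):
        raise ValueError(f"item {item_id!r} has no latent mean estimate")
    sd = float(row["latent_sd"].iloc[0])
    if not np.isfinite(sd):
        sd = 1.0
    return response_probs(mu, sd, thresholds, link)


def recovery_error(
    truth: pd.Series,
    estimates: pd.Series,
    scaled: bool = False,
):
    """Per-item recovery errors ``truth - estimate`` and their SD.

    With ``scaled=True`` both vectors are first divided by their own SDs
    across items, making the comparison invariant to estimate magnitude.
    """
    truth = pd.Series(truth).astype(float)
    estimates = pd.Series(estimates).astype(float)
    if set(truth.index) != set(estimates.index):
        raise ValueError("truth and estimates cover different item sets")
    estimates = estimates.reindex(truth.index)
    t, e = truth.to_numpy(), estimates.to_numpy()
    if scaled:
        t = t / np.std(t, ddof=1)
        e = e / np.std(e, ddof=1)
    err = t - e
    return pd.Series(err, index=truth.index), float(np.std(err, ddof=1))


@dataclass
class EvaluationReport:
    """Container for evaluation outputs: tables, summary stats, and seeds."""

    name: str
    seed: int
    summary: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def save(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {"name": self.name, "seed": self.seed, "summary": self.summary},
                fh,
                indent=1,
                default=float,
            )
        for key, df in self.tables.items():
            df.to_csv(out / f"{key}.csv", index=False)


_NORM_METHODS = {
    "raw": lambda trials, K: raw_norms(trials),
    "zscore": lambda trials, K: zscore_norms(trials),
    "lmm": lambda trials, K: lmm_norms(trials),
    "clmm_ml": lambda trials, K: clmm_ml_norms(trials, K),
}


def split_half_consistency(
    trials: pd.DataFrame,
    n_iterations: int,
    methods: tuple[str, ...] = ("raw", "lmm", "clmm_ml"),
    seed: int = 0,
    n_levels: int = 5,
) -> EvaluationReport:
    """Split-half consistency of norm estimates.

    Each iteration splits every item's trials randomly into halves A and B
    (an odd item's extra trial goes to A for even item indices, B for odd),
    norms both halves independently with each method, standardises each
    method's estimates by the SD of its estimates pooled over both halves,
    and records per-item A-B differences.
    """
    for m in methods:
        if m not in _NORM_METHODS:
            raise ValueError(f"unknown method {m!r}")
    counts = trials.groupby("item_id").size()
    keep = counts[counts >= 2].index
    dropped = len(counts) - len(keep)
    if dropped:
        logger.warning("excluding %d items with < 2 ratings from split-half",
                       dropped)
    trials = trials[trials["item_id"].isin(keep)]
    item_codes, _ = pd.factorize(trials["item_id"], sort=True)

    rng = np.random.default_rng(seed)
    sizes = np.bincount(item_codes)
    # odd counts: the extra trial goes to half A for even item indices,
    # half B for odd ones ("roughly equal" halves, deterministically)
    cutoff = sizes // 2 + ((np.arange(sizes.size) % 2 == 0) & (sizes % 2 == 1))
    records = []
    for it in range(n_iterations):
        u = rng.random(len(trials))
        order = np.lexsort((u, item_codes))  # sort by item, random within
        pos_sorted = np.arange(len(trials)) - np.repeat(
            np.concatenate(([0], np.cumsum(sizes)[:-1])), sizes
        )
        in_a_sorted = pos_sorted < np.repeat(cutoff, sizes)
        in_a = np.empty(len(trials), dtype=bool)
        in_a[order] = in_a_sorted

        half_a, half_b = trials[in_a], trials[~in_a]
        for method in methods:
            est_a = estimate_column(_NORM_METHODS[method](half_a, n_levels))
            est_b = estimate_column(_NORM_METHODS[method](half_b, n_levels))
            common = est_a.index.intersection(est_b.index)
            est_a, est_b = est_a[common], est_b[common]
            pooled_sd = float(np.std(np.concatenate([est_a, est_b]), ddof=1))
            diffs = (est_a - est_b) / pooled_sd
            records.append(
                pd.DataFrame(
                    {
                        "iteration": it,
                        "item_id": common,
                        "method": method,
                        "diff": diffs.to_numpy(),
                    }
                )
            )
    table = pd.concat(records, ignore_index=True)
    summary = {
        m: {
            "sd_of_diffs": float(
                table.loc[table["method"] == m, "diff"].std(ddof=1)
            )
        }
        for m in methods
    }
    report = EvaluationReport(
        name="split_half", seed=seed, summary=summary,
        tables={"differences": table},
    )
    return report


# ---------------------------------------------------------------------------
# experiment runner


def _scaled(base: int, scale: float, floor: int) -> int:
    return max(floor, int(round(base * scale)))


def run_experiment(
    sim_id: str,
    scale: float = 0.1,
    seed: int = 0,
    **overrides,
) -> EvaluationReport:
    """Run one of the simulation studies at a configurable scale.

    ``scale = 1`` reproduces the published designs (100 items x 100
    participants, 100/250 iterations, full SD grid); smaller values shrink
    the number of items/participants (floor 20) and iterations (floor 2)
    proportionally.
    """
    sim_id = str(sim_id)
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    if sim_id == "1":
        return _experiment_sim1(scale, seed, **overrides)
    if sim_id == "2":
        return _experiment_sim2(scale, seed, **overrides)
    if sim_id == "2b":
        return _experiment_sim2b(scale, seed, **overrides)
    if sim_id == "3":
        return _experiment_sim3(scale, seed, **overrides)
    if sim_id in ("4a", "4b"):
        return _experiment_sim4(sim_id, scale, seed, **overrides)
    raise ValueError(f"unknown simulation id {sim_id!r}")


_PATTERNS = (
    "equidistant", "left-biased", "right-biased", "edge-biased", "centre-biased"
)


def _experiment_sim1(scale, seed, n_items=None, ratings_per_item=25,
                     n_iterations=None, patterns=_PATTERNS):
    n_items = n_items or _scaled(100, scale, 20)
    n_iterations = n_iterations or _scaled(100, scale, 2)
    ss = np.random.SeedSequence(seed)
    iter_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_iterations)]
    rows = []
    mode_vectors: dict[tuple[int, str], pd.Series] = {}
    raw_vectors: dict[tuple[int, str], pd.Series] = {}
    for it, s in enumerate(iter_seeds):
        design = SimulationDesign(
            n_items=n_items, ratings_per_item=ratings_per_item,
            sd_mu_item=1.0, seed=s,
        )
        for pat in patterns:
            trials = simulate_items_only(design, pattern=pat)
            truth = trials.groupby("item_id")["mu_item"].first()
            norms = clmm_ml_norms(trials, 5, factors=("item",))
            modes = estimate_column(norms)
            raw = trials.groupby("item_id")["response"].mean()
            mode_vectors[(it, pat)] = modes
            raw_vectors[(it, pat)] = raw
            rows.append(
                {
                    "iteration": it,
                    "pattern": pat,
                    "r_modes": float(np.corrcoef(truth, modes[truth.index])[0, 1]),
                    "r_raw": float(np.corrcoef(truth, raw[truth.index])[0, 1]),
                    "seed": s,
                }
            )
    table = pd.DataFrame(rows)
    # cross-pattern agreement (the same latent data recoded five ways)
    xrows = []
    for it in range(n_iterations):
        for a in range(len(patterns)):
            for b in range(a + 1, len(patterns)):
                ma = mode_vectors[(it, patterns[a])]
                mb = mode_vectors[(it, patterns[b])]
                ra = raw_vectors[(it, patterns[a])]
                rb = raw_vectors[(it, patterns[b])]
                xrows.append(
                    {
                        "iteration": it,
                        "pattern_a": patterns[a],
                        "pattern_b": patterns[b],
                        "r_modes": float(np.corrcoef(ma, mb[ma.index])[0, 1]),
                        "r2_modes": float(
                            np.corrcoef(ma, mb[ma.index])[0, 1] ** 2
                        ),
                        "r2_raw": float(
                            np.corrcoef(ra, rb[ra.index])[0, 1] ** 2
                        ),
                    }
                )
    cross = pd.DataFrame(xrows)
    summary = {
        "median_r_modes_by_pattern": {
            p: float(table.loc[table["pattern"] == p, "r_modes"].median())
            for p in patterns
        },
        "min_cross_pattern_r": float(cross["r_modes"].min()),
        "n_items": n_items,
        "n_iterations": n_iterations,
    }
    return EvaluationReport("sim1", seed, summary,
                            {"recovery": table, "cross_pattern": cross})


def _crossed_design(scale, s, sd_item=1.0, sd_part=1.0, sd_disc_i=0.0,
                    sd_disc_j=0.0, n_units=None):
    n = n_units or _scaled(100, scale, 20)
    return SimulationDesign(
        n_items=n, n_participants=n, ratings_per_item=25,
        items_per_participant=25, sd_mu_item=sd_item, sd_mu_participant=sd_part,
        sd_disc_item=sd_disc_i, sd_disc_participant=sd_disc_j, seed=s,
    )


def _sim2_error_sds(trials, truth, n_levels=5):
    """Scaled error SD for item-only and item+participant CLMMs."""
    out = {}
    for label, factors in (("item_only", ("item",)),
                           ("item_participant", ("item", "participant"))):
        norms = clmm_ml_norms(trials, n_levels, factors=factors)
        est = estimate_column(norms)
        _, sd_scaled = recovery_error(truth, est, scaled=True)
        _, sd_raw = recovery_error(truth, est, scaled=False)
        out[label] = {"sd_scaled_error": sd_scaled, "sd_error": sd_raw}
    return out


def _experiment_sim2(scale, seed, n_iterations=None, patterns=_PATTERNS,
                     n_units=None):
    n_iterations = n_iterations or _scaled(100, scale, 2)
    ss = np.random.SeedSequence(seed)
    iter_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_iterations)]
    rows = []
    for it, s in enumerate(iter_seeds):
        design = _crossed_design(scale, s, n_units=n_units)
        for pat in patterns:
            trials = simulate_crossed(design, pattern=pat)
            truth = trials.groupby("item_id")["mu_item"].first()
            res = _sim2_error_sds(trials, truth)
            for label, stats in res.items():
                rows.append(
                    {"iteration": it, "pattern": pat, "model": label,
                     "seed": s, **stats}
                )
    table = pd.DataFrame(rows)
    summary = {
        "mean_sd_scaled_error": {
            label: float(
                table.loc[table["model"] == label, "sd_scaled_error"].mean()
            )
            for label in ("item_only", "item_participant")
        },
        "n_iterations": n_iterations,
    }
    return EvaluationReport("sim2", seed, summary, {"errors": table})


def _experiment_sim2b(scale, seed, grid=None, n_iterations=None, n_units=None):
    if grid is None:
        grid = (
            tuple(np.arange(0.25, 5.01, 0.25))
            if scale >= 1
            else (0.25, 1.0, 2.0, 5.0)
        )
    n_iterations = n_iterations or _scaled(50, scale, 2)
    ss = np.random.SeedSequence(seed)
    rows = []
    for sd_item in grid:
        for sd_part in grid:
            cell_seeds = np.random.SeedSequence(
                entropy=seed, spawn_key=(int(sd_item * 100), int(sd_part * 100))
            ).spawn(n_iterations)
            for it, cs in enumerate(cell_seeds):
                s = int(cs.generate_state(1)[0])
                design = _crossed_design(
                    scale, s, sd_item=sd_item, sd_part=sd_part, n_units=n_units
                )
                trials = simulate_crossed(design, pattern="edge-biased")
                truth = trials.groupby("item_id")["mu_item"].first()
                res = _sim2_error_sds(trials, truth)
                for label, stats in res.items():
                    rows.append(
                        {"sd_item": sd_item, "sd_participant": sd_part,
                         "iteration": it, "model": label, "seed": s, **stats}
                    )
    table = pd.DataFrame(rows)
    pivot = (
        table.groupby(["sd_item", "sd_participant", "model"])["sd_scaled_error"]
        .mean()
        .unstack("model")
    )
    pivot["gain"] = pivot["item_only"] - pivot["item_participant"]
    summary = {"max_gain": float(pivot["gain"].max()),
               "n_iterations": n_iterations, "grid": list(grid)}
    return EvaluationReport("sim2b", seed, summary,
                            {"errors": table, "gain": pivot.reset_index()})


def _experiment_sim3(scale, seed, n_iterations=None, n_units=None,
                     patterns=("edge-biased",), chains=4, iterations=900,
                     warmup=450):
    from latentnorm.clmm_bayes import (
        DistributionalSpec,
        fit_distributional,
        summarize_posterior_norms,
    )

    n_iterations = n_iterations or _scaled(100, scale, 1)
    n_units = n_units or _scaled(100, scale, 20)
    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.spawn(n_iterations)
    rows = []
    for it, cs in enumerate(iter_seeds):
        s = int(cs.generate_state(1)[0])
        design = _crossed_design(scale, s, sd_disc_i=0.5, sd_disc_j=0.5,
                                 n_units=n_units)
        for pat in patterns:
            trials = simulate_crossed(design, pattern=pat)
            truth_mu = trials.groupby("item_id")["mu_item"].first()
            truth_sd = 1.0 / np.exp(trials.groupby("item_id")["disc_item"].first())
            spec = DistributionalSpec(
                n_levels=5, chains=chains, iterations=iterations,
                warmup=warmup, seed=s, strict=False,
            )
            post = fit_distributional(trials, spec)
            norms = summarize_posterior_norms(post, trials)
            est = norms.set_index("item_id")
            r_mu = float(
                np.corrcoef(truth_mu, est["latent_mean"][truth_mu.index])[0, 1]
            )
            rho_sd = float(
                pd.Series(truth_sd).corr(
                    pd.Series(est["latent_sd"][truth_sd.index]),
                    method="spearman",
                )
            )
            rows.append(
                {"iteration": it, "pattern": pat, "r_latent_mean": r_mu,
                 "spearman_latent_sd": rho_sd, "seed": s,
                 "max_rhat": float(max(post.rhat.values()))}
            )
    table = pd.DataFrame(rows)
    summary = {
        "median_r_latent_mean": float(table["r_latent_mean"].median()),
        "median_spearman_latent_sd": float(table["spearman_latent_sd"].median()),
        "n_iterations": n_iterations,
    }
    return EvaluationReport("sim3", seed, summary, {"recovery": table})


def _experiment_sim4(sim_id, scale, seed, n_iterations=None, n_units=None,
                     dists=("normal", "logistic", "uniform", "bimodal",
                            "halfnormal")):
    target = "latent_residual" if sim_id == "4a" else "item_re"
    n_iterations = n_iterations or _scaled(250, scale, 2)
    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.spawn(n_iterations)
    rows = []
    for it, cs in enumerate(iter_seeds):
        s = int(cs.generate_state(1)[0])
        design = _crossed_design(scale, s, n_units=n_units)
        for dist in dists:
            trials = simulate_nonnormal(design, target, dist,
                                        pattern="edge-biased")
            truth = trials.groupby("item_id")["mu_item"].first()
            norms = clmm_ml_norms(trials, 5)
            modes = estimate_column(norms)
            raw = trials.groupby("item_id")["response"].mean()
            rows.append(
                {
                    "iteration": it, "dist": dist, "seed": s,
                    "r_modes": float(
                        np.corrcoef(truth, modes[truth.index])[0, 1]
                    ),
                    "r_raw": float(np.corrcoef(truth, raw[truth.index])[0, 1]),
                }
            )
    table = pd.DataFrame(rows)
    summary = {
        dist: {
            "median_r_modes": float(
                table.loc[table["dist"] == dist, "r_modes"].median()
            ),
            "median_r_raw": float(
                table.loc[table["dist"] == dist, "r_raw"].median()
            ),
        }
        for dist in dists
    }
    summary["n_iterations"] = n_iterations
    return EvaluationReport(f"sim{sim_id}", seed, summary, {"recovery": table})
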