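"""Node-permutation null for strength-consistency class effects.

Each null replicate relabels the females within every group-year's
annual DSI matrix (a uniform permutation of the roster applied jointly
to rows and columns, so dyadic values are conserved and only identities
move), then re-runs the downstream pipeline — top-k partners, bond
strength, multi-year consistency, class assignment — and refits the
fixed-time Cox model.  Non-network covariates (dominance rank, group
size, age at first birth) are never permuted.  The reported quantity per
class contrast is the proportion of null coefficients below the
observed one, exactly the one-sided summary a permutation table reports;
two-sided conversion is left to the caller.

Permutations are independent across group-years and across replicates;
replicate seeds are split off a master seed, so the full null
distribution is reproducible bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _cox, partners
from .pipeline import Study

log = logging.getLogger("socbond")


@dataclass
class PermutationResult:
    term: str
    beta_observed: float
    beta_null: np.ndarray
    prop_null_less: float
    n_valid: int
    n_failed: int
    unreliable: bool


def permute_nodes(dyads: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Relabel every group-year's roster by an independent uniform permutation.

    Dyadic values travel with the pair, so each group-year's multiset of
    DSI values is conserved; the two directional resting components
    follow their (relabelled) focal members.  Rosters smaller than 2 are
    returned unchanged.
    """
    out = dyads.copy()
    for (g, y), d in dyads.groupby(["group_id", "year"], sort=True):
        roster = sorted(set(d["id_i"]) | set(d["id_j"]))
        if len(roster) < 2:
            continue
        perm = dict(zip(roster, np.array(roster)[rng.permutation(len(roster))]))
        ni = d["id_i"].map(perm).to_numpy()
        nj = d["id_j"].map(perm).to_numpy()
        swap = ni > nj
        out.loc[d.index, "id_i"] = np.where(swap, nj, ni)
        out.loc[d.index, "id_j"] = np.where(swap, ni, nj)
        if "R_ij" in out.columns:
            rij = d["R_ij"].to_numpy()
            rji = d["R_ji"].to_numpy()
            out.loc[d.index, "R_ij"] = np.where(swap, rji, rij)
            out.loc[d.index, "R_ji"] = np.where(swap, rij, rji)
    return out


class _FixedModelNull:
    """Pre-compiled fixed-time pipeline for fast null refits.

    Caches the dyad-table structure (per group-year row indices into the
    roster) and the static per-female survival data and unpermuted
    covariates; each replicate only redoes label assignment, top-k
    metrics, class thresholds and the Newton fit.
    """

    def __init__(self, study: Study, competition: str = "rank", k: int | None = None,
                 recompute_thresholds: bool = True):
        self.k = k or study.config.k_top
        self.recompute_thresholds = recompute_thresholds
        dy = study.dyads
        self.groupyears = []
        for (g, y), d in dy.groupby(["group_id", "year"], sort=True):
            roster = sorted(set(d["id_i"]) | set(d["id_j"]))
            idx = {f: i for i, f in enumerate(roster)}
            self.groupyears.append(
                (
                    y,
                    np.array(roster, dtype=object),
                    d["id_i"].map(idx).to_numpy(),
                    d["id_j"].map(idx).to_numpy(),
                    d["dsi"].to_numpy(),
                )
            )
        cov = {"rank": "mean_rank", "groupmates": "mean_groupmates"}[competition]
        rec = study.fixed_records(self.k).dropna(subset=[cov, "age_first_birth"])
        self.females = rec["female_id"].to_numpy()
        self.fset = set(self.females)
        self.entry = rec["entry_age"].to_numpy(float)
        self.stop = rec["exit_age"].to_numpy(float)
        self.event = rec["event"].to_numpy(int)
        from .survival import standardize

        self.static = np.column_stack(
            [standardize(rec["age_first_birth"], "age_first_birth"),
             standardize(rec[cov], cov)]
        )
        self.static_names = ["age_first_birth", cov]
        self.levels = [1, 2, 4]  # dummies against reference class 3
        self.term_names = [f"class_multi[{l}]" for l in self.levels]
        obs_classes = rec["class_multi"].astype(int).to_numpy()
        # thresholds of the observed classification, for the fixed-threshold
        # variant of the null
        self.s_thr = float(rec["bond_strength_multi"].mean())
        self.c_thr = float(rec["consistency_multi"].mean())
        self.observed_beta = self._fit(obs_classes)

    def metrics(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """One permuted pipeline pass -> (strength, consistency, mask) over females."""
        per_female: dict[str, dict[int, list[tuple[float, str]]]] = {}
        for y, roster, ii, jj, vals in self.groupyears:
            labels = roster[rng.permutation(len(roster))]
            li = labels[ii]
            lj = labels[jj]
            for a, b, v in zip(li, lj, vals):
                per_female.setdefault(a, {}).setdefault(y, []).append((-v, b))
                per_female.setdefault(b, {}).setdefault(y, []).append((-v, a))
        k = self.k
        strength = np.full(len(self.females), np.nan)
        consistency = np.full(len(self.females), np.nan)
        for fi, f in enumerate(self.females):
            yrs = per_female.get(f)
            if not yrs or len(yrs) < 2:
                continue
            seq = []
            s_sum = 0.0
            for y in sorted(yrs):
                lst = sorted(yrs[y])[:k]
                seq.append([p for _, p in lst])
                s_sum += -np.mean([v for v, _ in lst])
            strength[fi] = s_sum / len(seq)
            consistency[fi] = partners.multi_year_consistency(seq)
        mask = ~np.isnan(strength) & ~np.isnan(consistency)
        return strength, consistency, mask

    def _fit(self, classes: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        if mask is None:
            mask = np.ones(len(classes), dtype=bool)
        cm = classes[mask]
        dummies = np.column_stack([(cm == l).astype(float) for l in self.levels])
        X = np.column_stack([dummies, self.static[mask]])
        fit = _cox.cox_fit(self.entry[mask], self.stop[mask], self.event[mask], X)
        return fit.beta[: len(self.levels)]

    def null_beta(self, rng: np.random.Generator) -> np.ndarray | None:
        strength, consistency, mask = self.metrics(rng)
        if mask.sum() < 8 or self.event[mask].sum() == 0:
            return None
        classes = np.zeros(len(self.females), dtype=int)
        if self.recompute_thresholds:
            classes[mask] = partners.assign_classes(strength[mask], consistency[mask])
        else:
            s_hi = strength[mask] > self.s_thr
            c_hi = consistency[mask] > self.c_thr
            classes[mask] = np.select(
                [~s_hi & ~c_hi, ~s_hi & c_hi, s_hi & ~c_hi], [1, 2, 3], default=4
            )
        try:
            return self._fit(classes, mask)
        except (ValueError, _cox.SeparationError, np.linalg.LinAlgError):
            return None


def permutation_test(
    study: Study,
    competition: str = "rank",
    n_permutations: int = 1000,
    seed: int = 0,
    k: int | None = None,
    recompute_thresholds: bool = True,
) -> dict[str, PermutationResult]:
    """Node-permutation test of the class contrasts in the fixed-time model.

    Returns one :class:`PermutationResult` per class contrast (classes
    1, 2 and 4 versus the reference class 3).  A result is flagged
    unreliable when more than 20% of null fits fail.
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive")
    eng = _FixedModelNull(study, competition=competition, k=k,
                          recompute_thresholds=recompute_thresholds)
    seeds = np.random.SeedSequence(seed).spawn(n_permutations)
    nulls = []
    n_failed = 0
    for ss in seeds:
        b = eng.null_beta(np.random.default_rng(ss))
        if b is None:
            n_failed += 1
        else:
            nulls.append(b)
    nulls = np.array(nulls) if nulls else np.empty((0, len(eng.levels)))
    unreliable = n_failed > 0.2 * n_permutations
    if unreliable:
        log.warning("%d of %d null fits failed; permutation result unreliable",
                    n_failed, n_permutations)
    out = {}
    for j, term in enumerate(eng.term_names):
        obs = float(eng.observed_beta[j])
        bn = nulls[:, j]
        out[term] = PermutationResult(
            term=term,
            beta_observed=obs,
            beta_null=bn,
            prop_null_less=float((bn < obs).mean()) if len(bn) else np.nan,
            n_valid=len(bn),
            n_failed=n_failed,
            unreliable=unreliable,
        )
    return out
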