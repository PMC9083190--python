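"""Synthetic response cohorts with controlled group separation.

Two outcome groups (immune-mediated outcome vs. not) are simulated by
drawing each participant's answers independently per question from a
group-specific :class:`GroupProfile`:

* ``single_choice`` / ``boolean`` questions: one categorical draw over the
  listed options, with the probability mass not assigned to any option
  interpreted as "no selection";
* ``multi_choice`` questions: an independent Bernoulli draw per option.

Answers are independent across questions (no symptom co-occurrence
structure — deliberately the simplest generative model that exercises the
whole score → evaluate pipeline). Cohorts are exactly reproducible from the
root seed; the outcome-positive fraction is ``n_pos / (n_pos + n_neg)`` by
construction.

``calibrate_separation`` tunes how far the positive group's profile sits
between the negative and positive base profiles (geometric/logit-scale
interpolation with coefficient ``lam`` in [0, 1], found by bisection over
Monte-Carlo AUC estimates) so the expected total-score AUC hits a target.
Shipped presets mirror the cohort shapes of a three-center validation
study — sizes 21+29, 28+23 and 51+22 with total-score AUC targets 0.753,
0.790 and 0.536 — emulating those cohorts' statistical shape only, not any
clinical content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .cohort import ScoredCohort, score_cohort
from .config import ScoringConfig, default_config
from .exceptions import SimulationError
from .scoring import ResponseSet
from .stats import _mann_whitney_auc

_EPS = 1e-9


@dataclass(frozen=True)
class GroupProfile:
    """Per-question option-selection probabilities for one outcome group."""

    probs: dict[str, dict[str, float]]

    def validate(self, config: ScoringConfig) -> None:
        qindex = config.question_by_id()
        for qid, opts in self.probs.items():
            q = qindex.get(qid)
            if q is None:
                raise SimulationError(f"profile references unknown question {qid!r}")
            known = {o.id for o in q.options}
            for oid, p in opts.items():
                if oid not in known:
                    raise SimulationError(
                        f"profile question {qid!r}: unknown option {oid!r}"
                    )
                if not 0.0 <= p <= 1.0:
                    raise SimulationError(
                        f"profile question {qid!r} option {oid!r}: probability "
                        f"{p} outside [0, 1]"
                    )
            if q.kind in ("single_choice", "boolean"):
                total = sum(opts.values())
                if total > 1.0 + 1e-9:
                    raise SimulationError(
                        f"profile question {qid!r}: option probabilities sum to "
                        f"{total:.6f} > 1 for a {q.kind} question"
                    )


@dataclass(frozen=True)
class SimConfig:
    config: ScoringConfig
    n_pos: int
    n_neg: int
    profile_pos: GroupProfile
    profile_neg: GroupProfile
    seed: int
    name: str = "simulated"
    mixing: float | None = None  # set by calibrate_separation
    calibrated_auc: float | None = None

    def validate(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise SimulationError("n_pos and n_neg must both be >= 1")
        self.profile_pos.validate(self.config)
        self.profile_neg.validate(self.config)


def default_profiles() -> tuple[GroupProfile, GroupProfile]:
    """The shipped (negative, positive) base profiles for the default config."""
    raw = json.loads(
        resources.files("rheumascore.data")
        .joinpath("default_profiles.json")
        .read_text(encoding="utf-8")
    )
    return GroupProfile(raw["negative"]), GroupProfile(raw["positive"])


def load_profiles(path: str | Path) -> tuple[GroupProfile, GroupProfile]:
    """Load ``{"negative": {...}, "positive": {...}}`` from a JSON file."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    for key in ("negative", "positive"):
        if key not in raw:
            raise SimulationError(f"profile file {path}: missing group {key!r}")
    return GroupProfile(raw["negative"]), GroupProfile(raw["positive"])


# ---------------------------------------------------------------------------
# sampling core


def _draw_selections(
    config: ScoringConfig,
    profile: GroupProfile,
    n: int,
    rng: np.random.Generator,
) -> list[dict[str, frozenset[str]]]:
    """Draw ``n`` participants' selections, vectorised question by question."""
    per_participant: list[dict[str, frozenset[str]]] = [dict() for _ in range(n)]
    for q in config.questions:
        opts = profile.probs.get(q.id)
        if not opts:
            continue
        if q.kind in ("single_choice", "boolean"):
            oids = [o.id for o in q.options if o.id in opts]
            p = np.array([opts[o] for o in oids])
            cum = np.cumsum(p)
            u = rng.random(n)
            idx = np.searchsorted(cum, u, side="right")
            for i, k in enumerate(idx):
                if k < len(oids):
                    per_participant[i][q.id] = frozenset([oids[k]])
        else:  # multi_choice: independent per option
            oids = [o.id for o in q.options if o.id in opts]
            draws = {o: rng.random(n) < opts[o] for o in oids}
            for i in range(n):
                chosen = frozenset(o for o in oids if draws[o][i])
                if chosen:
                    per_participant[i][q.id] = chosen
    return per_participant


def simulate_cohort(sim: SimConfig) -> list[tuple[ResponseSet, int]]:
    """Generate ``n_pos + n_neg`` labelled response sets, reproducibly.

    Positive-outcome participants come first, then negatives; all sampling
    derives from ``sim.seed`` so the same seed yields a byte-identical
    cohort.
    """
    sim.validate()
    rng = np.random.default_rng(sim.seed)
    out: list[tuple[ResponseSet, int]] = []
    for group, profile, outcome in [
        ("pos", sim.profile_pos, 1),
        ("neg", sim.profile_neg, 0),
    ]:
        n = sim.n_pos if outcome == 1 else sim.n_neg
        sels = _draw_selections(sim.config, profile, n, rng)
        start = len(out)
        for i, sel in enumerate(sels):
            out.append(
                (ResponseSet(f"sim-{start + i + 1:05d}", sel), outcome)
            )
    return out


def simulate_scored_cohort(sim: SimConfig) -> ScoredCohort:
    """Simulate and score in one step."""
    pairs = simulate_cohort(sim)
    cohort, _ = score_cohort(sim.config, pairs, name=sim.name)
    return cohort


def _total_weight_arrays(config: ScoringConfig):
    """Per-question arrays of each option's total (summed-over-disease) weight."""
    out = []
    for q in config.questions:
        out.append((q, {o.id: sum(o.weights.values()) for o in q.options}))
    return out


def _sample_total_scores(
    config: ScoringConfig,
    profile: GroupProfile,
    n: int,
    rng: np.random.Generator,
    weights=None,
) -> np.ndarray:
    """Fast path: total scores only, same generative model as simulate_cohort."""
    weights = weights or _total_weight_arrays(config)
    scores = np.zeros(n)
    for q, wmap in weights:
        opts = profile.probs.get(q.id)
        if not opts:
            continue
        if q.kind in ("single_choice", "boolean"):
            oids = [o.id for o in q.options if o.id in opts]
            p = np.array([opts[o] for o in oids])
            w = np.array([wmap[o] for o in oids] + [0.0])
            idx = np.searchsorted(np.cumsum(p), rng.random(n), side="right")
            scores += w[idx]
        else:
            for o in q.options:
                if o.id in opts:
                    scores += wmap[o.id] * (rng.random(n) < opts[o.id])
    return scores


# ---------------------------------------------------------------------------
# profile interpolation and AUC calibration


def mix_profiles(neg: GroupProfile, pos: GroupProfile, lam: float,
                 config: ScoringConfig) -> GroupProfile:
    """Interpolate between two profiles on the log/logit scale.

    ``lam = 0`` returns the negative profile exactly, ``lam = 1`` the
    positive one. Categorical questions (including the implicit
    no-selection mass) are mixed geometrically and renormalised, which for
    two categories reduces to linear interpolation of the log-odds.
    """
    if lam == 0.0:
        return neg
    if lam == 1.0:
        return pos
    qindex = config.question_by_id()
    mixed: dict[str, dict[str, float]] = {}
    qids = set(neg.probs) | set(pos.probs)
    for qid in qids:
        q = qindex[qid]
        pn = neg.probs.get(qid, {})
        pp = pos.probs.get(qid, {})
        oids = [o.id for o in q.options if o.id in pn or o.id in pp]
        if q.kind in ("single_choice", "boolean"):
            vn = np.array([pn.get(o, 0.0) for o in oids] + [1.0 - sum(pn.values())])
            vp = np.array([pp.get(o, 0.0) for o in oids] + [1.0 - sum(pp.values())])
            vn = np.clip(vn, _EPS, None)
            vp = np.clip(vp, _EPS, None)
            logv = (1.0 - lam) * np.log(vn) + lam * np.log(vp)
            v = np.exp(logv - logv.max())
            v /= v.sum()
            mixed[qid] = {o: float(v[i]) for i, o in enumerate(oids)}
        else:
            out = {}
            for o in oids:
                a = np.clip(pn.get(o, 0.0), _EPS, 1.0 - _EPS)
                b = np.clip(pp.get(o, 0.0), _EPS, 1.0 - _EPS)
                logit = (1.0 - lam) * np.log(a / (1 - a)) + lam * np.log(b / (1 - b))
                out[o] = float(1.0 / (1.0 + np.exp(-logit)))
            mixed[qid] = out
    return GroupProfile(mixed)


def _expected_auc(
    sim: SimConfig, lam: float, n_eval: int, eval_seed: int, weights
) -> float:
    """Monte-Carlo estimate of the total-score AUC at mixing ``lam``.

    A fixed evaluation seed gives common random numbers across ``lam``
    values, so the bisection sees a smooth monotone curve.
    """
    profile = mix_profiles(sim.profile_neg, sim.profile_pos, lam, sim.config)
    rng = np.random.default_rng(eval_seed)
    pos_scores = _sample_total_scores(sim.config, profile, n_eval, rng, weights)
    neg_scores = _sample_total_scores(sim.config, sim.profile_neg, n_eval, rng, weights)
    return _mann_whitney_auc(pos_scores, neg_scores)


def calibrate_separation(
    sim: SimConfig,
    target_auc: float,
    *,
    tol: float = 0.005,
    n_eval: int = 4000,
) -> SimConfig:
    """Return a SimConfig whose expected total-score AUC hits ``target_auc``.

    The positive group's profile is replaced by the mixture
    ``mix_profiles(profile_neg, profile_pos, lam)`` with ``lam`` found by
    bisection over Monte-Carlo AUC estimates (``n_eval`` simulated
    participants per group per evaluation). Raises
    :class:`SimulationError`, reporting the achievable maximum, when the
    base profiles cannot reach the target.
    """
    if not 0.5 <= target_auc < 1.0:
        raise SimulationError(
            f"target AUC must be in [0.5, 1.0), got {target_auc}"
        )
    sim.validate()
    weights = _total_weight_arrays(sim.config)
    eval_seed = (sim.seed * 1_000_003 + 12345) % (2**31)
    if target_auc <= 0.5 + 1e-12:
        return replace(
            sim, profile_pos=sim.profile_neg, mixing=0.0, calibrated_auc=0.5
        )
    max_auc = _expected_auc(sim, 1.0, n_eval, eval_seed, weights)
    if max_auc < target_auc - tol:
        raise SimulationError(
            f"target AUC {target_auc:.3f} unattainable: the base profiles "
            f"reach at most {max_auc:.3f}"
        )
    lo, hi = 0.0, 1.0
    lam = 1.0
    auc = max_auc
    for _ in range(40):
        lam = 0.5 * (lo + hi)
        auc = _expected_auc(sim, lam, n_eval, eval_seed, weights)
        if abs(auc - target_auc) <= tol and (hi - lo) < 0.05:
            break
        if auc < target_auc:
            lo = lam
        else:
            hi = lam
        if hi - lo < 1e-5:
            break
    mixed = mix_profiles(sim.profile_neg, sim.profile_pos, lam, sim.config)
    return replace(sim, profile_pos=mixed, mixing=lam, calibrated_auc=float(auc))


# ---------------------------------------------------------------------------
# presets


#: Cohort shapes of the three validation centers: group sizes and the
#: total-score AUC each preset is calibrated to.
PRESETS: dict[str, dict] = {
    "dataset_A": {"n_pos": 21, "n_neg": 29, "target_auc": 0.753},
    "dataset_B": {"n_pos": 28, "n_neg": 23, "target_auc": 0.790},
    "dataset_C": {"n_pos": 51, "n_neg": 22, "target_auc": 0.536},
}


def preset_sim_config(
    name: str,
    *,
    config: ScoringConfig | None = None,
    seed: int = 0,
    calibrate: bool = True,
    n_pos: int | None = None,
    n_neg: int | None = None,
) -> SimConfig:
    """Build a (by default calibrated) preset simulation configuration."""
    if name not in PRESETS:
        raise SimulationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    spec = PRESETS[name]
    config = config or default_config()
    neg, pos = default_profiles()
    sim = SimConfig(
        config=config,
        n_pos=n_pos if n_pos is not None else spec["n_pos"],
        n_neg=n_neg if n_neg is not None else spec["n_neg"],
        profile_pos=pos,
        profile_neg=neg,
        seed=seed,
        name=name,
    )
    if calibrate:
        sim = calibrate_separation(sim, spec["target_auc"])
    return sim
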