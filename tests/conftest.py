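"""Shared fixtures: minimal and randomly generated toy instruments."""

from __future__ import annotations

import numpy as np
import pytest

from rheumascore import ResponseSet, ScoringConfig, default_config


def make_minimal_config(t1: int = 15, t2: int = 30) -> ScoringConfig:
    """Smallest legal instrument: one disease, one boolean question."""
    return ScoringConfig.model_validate(
        {
            "version": "1",
            "diseases": [{"id": "RA", "name": "Rheumatoid arthritis"}],
            "questions": [
                {
                    "id": "q1",
                    "text": "Swollen joints?",
                    "kind": "boolean",
                    "options": [
                        {"id": "yes", "label": "Yes", "weights": {"RA": 10}},
                        {"id": "no", "label": "No", "weights": {}},
                    ],
                }
            ],
            "thresholds": [{"disease_id": "RA", "threshold1": t1, "threshold2": t2}],
        }
    )


def make_toy_config(
    rng: np.random.Generator,
    *,
    max_diseases: int = 3,
    max_questions: int = 10,
    max_options: int = 4,
    allow_negative: bool = False,
) -> ScoringConfig:
    """A random small but valid instrument."""
    n_dis = int(rng.integers(1, max_diseases + 1))
    diseases = [{"id": f"d{i}", "name": f"Disease {i}"} for i in range(n_dis)]
    n_q = int(rng.integers(1, max_questions + 1))
    questions = []
    for qi in range(n_q):
        kind = rng.choice(["single_choice", "multi_choice", "boolean"])
        n_opt = 2 if kind == "boolean" else int(rng.integers(2, max_options + 1))
        options = []
        for oi in range(n_opt):
            weights = {}
            for di in range(n_dis):
                if rng.random() < 0.6:
                    lo = -20 if allow_negative else 0
                    weights[f"d{di}"] = int(rng.integers(lo, 51))
            options.append(
                {"id": f"o{oi}", "label": f"Option {oi}", "weights": weights}
            )
        questions.append(
            {
                "id": f"q{qi}",
                "text": f"Question {qi}?",
                "kind": str(kind),
                "options": options,
            }
        )
    # guarantee every disease has a nonzero weight somewhere
    for di in range(n_dis):
        q = questions[int(rng.integers(0, n_q))]
        opt = q["options"][int(rng.integers(0, len(q["options"])))]
        opt["weights"][f"d{di}"] = int(rng.integers(1, 51))
    thresholds = []
    for di in range(n_dis):
        t1 = int(rng.integers(1, 80))
        thresholds.append(
            {
                "disease_id": f"d{di}",
                "threshold1": t1,
                "threshold2": t1 + int(rng.integers(0, 80)),
            }
        )
    return ScoringConfig.model_validate(
        {
            "version": "1",
            "diseases": diseases,
            "questions": questions,
            "thresholds": thresholds,
        }
    )


def make_random_responses(
    config: ScoringConfig, rng: np.random.Generator, participant_id: str = "p1"
) -> ResponseSet:
    """Random valid answers for ``config`` (questions skipped with prob 0.2)."""
    selections = {}
    for q in config.questions:
        if rng.random() < 0.2:
            continue
        oids = [o.id for o in q.options]
        if q.kind == "multi_choice":
            chosen = frozenset(o for o in oids if rng.random() < 0.5)
        else:
            chosen = frozenset([str(rng.choice(oids))])
        if chosen:
            selections[q.id] = chosen
    return ResponseSet(participant_id, selections)


@pytest.fixture
def minimal_config() -> ScoringConfig:
    return make_minimal_config()


@pytest.fixture(scope="session")
def shipped_config() -> ScoringConfig:
    return default_config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
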