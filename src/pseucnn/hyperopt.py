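"""Two-phase random search over the six-parameter CNN space.

The search space is the Cartesian product of six candidate lists
(3·3·3·3·4·2 = 648 combinations). Random search draws configurations
uniformly and independently, screens each cheaply with stratified 5-fold
cross-validation at 15 epochs (dual metrics: ACC primary, MCC tie-break),
then fine-evaluates the winner with 10-fold cross-validation at 30 epochs.
Every configuration is screened on the same seeded folds so the comparison
is fair; the whole trace is reproducible from (space, data, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .cnn_model import HyperParams, MappingMode, ShapeError, build_model
from .evaluation import CvResult, cross_validate

logger = logging.getLogger(__name__)

#: Default candidate lists for the six tunable knobs.
DEFAULT_CANDIDATES: dict[str, list] = {
    "reshape_dim": [6, 7, 8],
    "conv_kernel": [3, 4, 5],
    "conv_stride": [1, 2, 3],
    "dense_layers": [1, 2, 3],
    "dense_units": [4, 8, 16, 32],
    "activation": ["relu", "selu"],
}

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class SearchSpace:
    """Candidate lists, draw budget and master seed of one search."""

    candidates: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_CANDIDATES))
    n_iter: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(DEFAULT_CANDIDATES) - set(self.candidates)
        if missing:
            raise ValueError(f"candidate lists missing for {sorted(missing)}")
        for name, values in self.candidates.items():
            if not values:
                raise ValueError(f"empty candidate list for {name!r}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @property
    def size(self) -> int:
        out = 1
        for values in self.candidates.values():
            out *= len(values)
        return out


def sample_config(
    space: SearchSpace,
    draw_index: int,
    validator: Callable[[HyperParams], None] | None = None,
) -> HyperParams:
    """Draw one configuration, uniformly per field, deterministically.

    The draw is a pure function of (space.seed, draw_index). Combinations
    the validator rejects (e.g. a kernel larger than the grid, or a
    zero-pad grid too small for the features) are redrawn, and each
    rejection is logged.
    """
    rng = np.random.default_rng(np.random.SeedSequence([space.seed, draw_index]))
    for attempt in range(_MAX_REDRAWS):
        choice = {
            name: values[rng.integers(len(values))]
            for name, values in space.candidates.items()
        }
        try:
            hp = HyperParams(**choice)
            if validator is not None:
                validator(hp)
            return hp
        except (ShapeError, ValueError) as exc:
            logger.info("draw %d attempt %d rejected: %s", draw_index, attempt, exc)
    raise RuntimeError(f"no legal configuration found after {_MAX_REDRAWS} redraws")


def screen_config(
    hp: HyperParams,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    k: int = 5,
    epochs: int = 15,
    filters: int = 16,
    mode: MappingMode = "dense_projection",
) -> tuple[float, float]:
    """Cheap screening score: mean validation (ACC, MCC) over k seeded folds."""
    result = cross_validate(
        X, y, hp, k=k, epochs=epochs, seed=seed, filters=filters, mode=mode
    )
    return result.mean["acc"], result.mean["mcc"]


@dataclass
class SearchTrace:
    """Ordered record of every draw, the winner, and its fine evaluation."""

    records: list[dict]
    best_index: int
    best_hp: HyperParams
    final: CvResult
    space: SearchSpace

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "space": {
                "candidates": self.space.candidates,
                "n_iter": self.space.n_iter,
                "seed": self.space.seed,
            },
            "records": self.records,
            "best_index": self.best_index,
            "best_hp": asdict(self.best_hp),
            "final_mean": self.final.mean,
            "final_k": self.final.k,
            "final_epochs": self.final.epochs,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def leaderboard(self) -> pd.DataFrame:
        """Draws sorted by (ACC desc, MCC desc, draw asc)."""
        df = pd.DataFrame(self.records)
        return df.sort_values(
            ["acc", "mcc", "draw"], ascending=[False, False, True]
        ).reset_index(drop=True)

    def leaderboard_tsv(self, path: str | Path) -> None:
        self.leaderboard().to_csv(path, sep="\t", index=False, float_format="%.6f")


def random_search(
    space: SearchSpace,
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = None,
    filters: int = 16,
    mode: MappingMode = "dense_projection",
    screen_k: int = 5,
    screen_epochs: int = 15,
    final_k: int = 10,
    final_epochs: int = 30,
) -> SearchTrace:
    """Screen ``space.n_iter`` random configurations and fine-evaluate the winner.

    Selection: highest screening ACC, ties broken by higher MCC, remaining
    ties by earliest draw. The winner is then re-evaluated with
    ``final_k``-fold cross-validation at ``final_epochs`` epochs.
    """
    if seed is not None and seed != space.seed:
        space = SearchSpace(candidates=space.candidates, n_iter=space.n_iter, seed=seed)
    input_dim = np.asarray(X).shape[1]

    def validator(hp: HyperParams) -> None:
        build_model(hp, input_dim=input_dim, filters=filters, mode=mode)

    records: list[dict] = []
    for draw in range(space.n_iter):
        hp = sample_config(space, draw, validator=validator)
        acc, mcc = screen_config(
            hp, X, y, seed=space.seed, k=screen_k, epochs=screen_epochs,
            filters=filters, mode=mode,
        )
        records.append({"draw": draw, **asdict(hp), "acc": acc, "mcc": mcc})

    best = max(records, key=lambda r: (r["acc"], r["mcc"], -r["draw"]))
    best_hp = HyperParams(
        **{name: best[name] for name in DEFAULT_CANDIDATES}
    )
    final = cross_validate(
        X, y, best_hp, k=final_k, epochs=final_epochs, seed=space.seed,
        filters=filters, mode=mode,
    )
    return SearchTrace(
        records=records,
        best_index=best["draw"],
        best_hp=best_hp,
        final=final,
        space=space,
    )
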