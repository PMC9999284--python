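"""Core data container for longitudinal ordinal item responses.

The whole pipeline consumes a single in-memory format: an integer array of
shape (n_subjects, n_items, n_sessions) holding category codes 0..C-1, with
-1 marking a missing response.  Long-format CSV round-tripping matches the
register-style layout (one row per subject x session x item).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class LongitudinalOrdinalData:
    """Subjects x items x sessions ordinal responses with missingness.

    Parameters
    ----------
    responses : ndarray of int, shape (n_subjects, n_items, n_sessions)
        Category codes ``0..n_categories-1``; ``-1`` marks missing.
    n_categories : int
        Number of ordered response categories C.
    item_labels, session_labels : list of str, optional
        Defaults to ``item_1.. / session_1..``.
    covariates : DataFrame, optional
        Per-subject covariates (e.g. age- and gender-like columns) used by
        logistic dropout.
    """

    responses: np.ndarray
    n_categories: int = 4
    item_labels: list = field(default_factory=list)
    session_labels: list = field(default_factory=list)
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 3:
            raise ValueError(
                "responses must be (n_subjects, n_items, n_sessions), got "
                f"shape {self.responses.shape}"
            )
        obs = self.responses[self.responses != MISSING]
        if obs.size and (obs.min() < 0 or obs.max() >= self.n_categories):
            raise ValueError(
                f"responses must lie in 0..{self.n_categories - 1} or be -1"
            )
        if not self.item_labels:
            self.item_labels = [f"item_{i + 1}" for i in range(self.n_items)]
        if not self.session_labels:
            self.session_labels = [
                f"session_{t + 1}" for t in range(self.n_sessions)
            ]

    @property
    def n_subjects(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_sessions(self) -> int:
        return self.responses.shape[2]

    def observed_mask(self) -> np.ndarray:
        """Boolean (n_subjects, n_items, n_sessions) of non-missing cells."""
        return self.responses != MISSING

    def session_observed(self) -> np.ndarray:
        """Boolean (n_subjects, n_sessions): any item observed at session."""
        return self.observed_mask().any(axis=1)

    def n_per_session(self) -> np.ndarray:
        return self.session_observed().sum(axis=0)

    def is_monotone(self) -> bool:
        """True when observed sessions form a prefix for every subject."""
        obs = self.session_observed()
        # once missing, never observed again
        return not np.any(obs[:, 1:] & ~obs[:, :-1])

    # -- wide helpers ------------------------------------------------------

    def wide(self) -> np.ndarray:
        """(n_subjects, n_items * n_sessions) with items fastest within
        session; column order matches :meth:`wide_labels`."""
        return self.responses.transpose(0, 2, 1).reshape(self.n_subjects, -1)

    def wide_labels(self) -> list:
        return [
            f"{it}@{ses}"
            for ses in self.session_labels
            for it in self.item_labels
        ]

    # -- IO ----------------------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        sub, item, ses = np.meshgrid(
            np.arange(self.n_subjects),
            np.arange(self.n_items),
            np.arange(self.n_sessions),
            indexing="ij",
        )
        resp = self.responses.reshape(-1).astype(float)
        resp[resp == MISSING] = np.nan
        return pd.DataFrame(
            {
                "subject_id": sub.reshape(-1),
                "session": ses.reshape(-1) + 1,
                "item": item.reshape(-1) + 1,
                "response": resp,
            }
        )

    def to_csv(self, path, config=None) -> None:
        """Write long-format CSV; optional JSON sidecar with the generating
        configuration (written next to ``path`` with suffix .config.json)."""
        path = Path(path)
        self.to_long_frame().to_csv(path, index=False)
        if config is not None:
            sidecar = path.with_suffix(".config.json")
            sidecar.write_text(json.dumps(config, indent=2, default=_jsonify))

    @classmethod
    def from_long_frame(
        cls, df: pd.DataFrame, n_categories: int = 4
    ) -> "LongitudinalOrdinalData":
        required = {"subject_id", "session", "item", "response"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise ValueError(f"missing columns: {sorted(missing_cols)}")
        subjects = np.sort(df["subject_id"].unique())
        sessions = np.sort(df["session"].unique())
        items = np.sort(df["item"].unique())
        sub_ix = {s: i for i, s in enumerate(subjects)}
        ses_ix = {s: i for i, s in enumerate(sessions)}
        it_ix = {s: i for i, s in enumerate(items)}
        resp = np.full(
            (len(subjects), len(items), len(sessions)), MISSING, dtype=int
        )
        obs = df.dropna(subset=["response"])
        resp[
            obs["subject_id"].map(sub_ix).to_numpy(),
            obs["item"].map(it_ix).to_numpy(),
            obs["session"].map(ses_ix).to_numpy(),
        ] = obs["response"].to_numpy().astype(int)
        return cls(
            responses=resp,
            n_categories=n_categories,
            item_labels=[f"item_{i}" for i in items],
            session_labels=[f"session_{s}" for s in sessions],
        )

    @classmethod
    def from_csv(cls, path, n_categories: int = 4) -> "LongitudinalOrdinalData":
        return cls.from_long_frame(pd.read_csv(path), n_categories=n_categories)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)
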