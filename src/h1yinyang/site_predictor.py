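"""Sliding-window one-hot neural scorer for modification potential.

Each candidate acceptor residue (Ser/Thr, plus Tyr for phosphorylation)
is encoded as a window of one-hot blocks of 21 bits (20 amino acids plus
a shared pad/unknown symbol for flanks running past the termini), and a
small feed-forward network with one logistic hidden layer maps the
window to a modification potential in [0, 1].  Training uses k-fold
cross-validation to report held-out accuracy, then refits on the full
data set; scoring is a plain numpy forward pass over the stored weights,
so a serialized model reproduces its scores bit-identically.

This scorer is a generic window classifier of the family used by public
phosphorylation / O-GlcNAc predictors; it does not claim to replicate
any particular trained server, whose exported score tables can instead
be imported via :func:`import_scores`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .sequence_io import ALPHABET, ProteinRecord, SiteScore, read_score_table

PAD = "X"  # terminal padding / unknown residue symbol
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

DEFAULT_WINDOW = 9
DEFAULT_THRESHOLD = 0.5


def encode_window(record: ProteinRecord, position: int, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """One-hot encode the window centered on an S/T/Y residue.

    Returns a float vector of length ``window * 21`` — one 21-bit block
    per window cell, exactly one bit set per block; out-of-range flanks
    use the pad symbol's bit.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    center = record.residue_at(position)
    if center not in "STY":
        raise ValueError(f"{record.id}:{position}: window center must be S/T/Y, got {center!r}")
    half = window // 2
    vec = np.zeros(window * len(ALPHABET))
    for k, pos in enumerate(range(position - half, position + half + 1)):
        aa = record.sequence[pos - 1] if 1 <= pos <= len(record.sequence) else PAD
        vec[k * len(ALPHABET) + _INDEX[aa]] = 1.0
    return vec


@dataclass
class PredictorModel:
    """A trained window scorer: weights, threshold and training metadata."""

    window: int
    coefs: list[np.ndarray]       # [input->hidden, hidden->output]
    intercepts: list[np.ndarray]
    threshold: float = DEFAULT_THRESHOLD
    alphabet: str = ALPHABET
    predictor: str = "phospho"
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coefs[0].shape[0] != self.window * len(self.alphabet):
            raise ValueError(
                f"input dimension {self.coefs[0].shape[0]} != window {self.window} x {len(self.alphabet)}"
            )
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold {self.threshold} outside (0, 1)")

    def score_vector(self, x: np.ndarray) -> float:
        """Forward pass: logistic hidden layer, logistic output in [0, 1]."""
        h = _sigmoid(x @ self.coefs[0] + self.intercepts[0])
        out = _sigmoid(h @ self.coefs[1] + self.intercepts[1])
        return float(out.ravel()[0])

    def score(self, record: ProteinRecord, position: int) -> float:
        if self.alphabet != ALPHABET:
            raise ValueError(f"model alphabet {self.alphabet!r} does not match package alphabet")
        return self.score_vector(encode_window(record, position, self.window))

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "h1yinyang-predictor-v1",
            "window": self.window,
            "threshold": self.threshold,
            "alphabet": self.alphabet,
            "predictor": self.predictor,
            "coefs": [c.tolist() for c in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PredictorModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "h1yinyang-predictor-v1":
            raise ValueError(f"{path}: not a recognised model file")
        return cls(
            window=payload["window"],
            coefs=[np.asarray(c) for c in payload["coefs"]],
            intercepts=[np.asarray(b) for b in payload["intercepts"]],
            threshold=payload["threshold"],
            alphabet=payload["alphabet"],
            predictor=payload.get("predictor", "phospho"),
            training_meta=payload.get("training_meta", {}),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def train(
    examples: Sequence[tuple[ProteinRecord, int, int]],
    window: int = DEFAULT_WINDOW,
    folds: int = 5,
    seed: int = 0,
    epochs: int = 400,
    hidden_units: int = 4,
    threshold: float = DEFAULT_THRESHOLD,
    predictor: str = "phospho",
) -> PredictorModel:
    """Train the window scorer on (record, position, label) examples.

    Held-out accuracy is estimated by stratified k-fold cross-validation
    (a fresh network per fold), then the final network is refit on all
    examples.  All randomness flows from ``seed``; identical calls give
    identical weights.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = np.array([int(lab) for _, _, lab in examples])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set must contain both labels")
    X = np.stack([encode_window(rec, pos, window) for rec, pos, _ in examples])

    def make_net(rs: int) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=(hidden_units,),
            activation="logistic",
            solver="adam",
            learning_rate_init=0.01,  # the default 1e-3 can stall on the logistic plateau
            max_iter=epochs,
            # stop on a training-loss plateau; a held-out validation split is
            # too small to be reliable at the data sizes this scorer sees
            early_stopping=False,
            n_iter_no_change=25,
            random_state=rs,
        )

    fold_acc = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for k, (tr, te) in enumerate(skf.split(X, labels)):
        net = make_net(seed + 1 + k)
        net.fit(X[tr], labels[tr])
        fold_acc.append(float(net.score(X[te], labels[te])))

    final = make_net(seed)
    final.fit(X, labels)
    return PredictorModel(
        window=window,
        coefs=[np.asarray(c) for c in final.coefs_],
        intercepts=[np.asarray(b) for b in final.intercepts_],
        threshold=threshold,
        predictor=predictor,
        training_meta={
            "folds": folds,
            "seed": seed,
            "epochs": epochs,
            "hidden_units": hidden_units,
            "n_examples": len(examples),
            "fold_accuracy": fold_acc,
            "holdout_accuracy": float(np.mean(fold_acc)),
        },
    )


def predict_sites(model: PredictorModel, record: ProteinRecord) -> list[SiteScore]:
    """Score every candidate residue of a sequence.

    Ser and Thr are scored always; Tyr additionally for phosphorylation
    models (O-GlcNAc does not occur on Tyr).
    """
    residues = "STY" if model.predictor == "phospho" else "ST"
    out = []
    for pos in record.positions_of(residues):
        out.append(
            SiteScore(
                seq_id=record.id,
                position=pos,
                residue=record.residue_at(pos),
                predictor=model.predictor,
                score=min(1.0, max(0.0, model.score(record, pos))),
                threshold=model.threshold,
            )
        )
    return out


def import_scores(path: str | Path, predictor: str | None = None,
                  records: Iterable[ProteinRecord] | None = None) -> list[SiteScore]:
    """Import an external predictor's exported score table (TSV).

    Rows keep their own thresholds; ``predictor`` filters to one
    predictor column value when given.
    """
    scores = read_score_table(path, records=list(records) if records is not None else None)
    if predictor is not None:
        scores = [s for s in scores if s.predictor == predictor]
    return scores
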