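"""End-to-end orchestration of the secure disease-prediction pipeline.

Sender side (:func:`secure_upload`): verify the uploader's credentials,
serialize the raw patient table, encrypt it with LR-ECC under the
sender-private / receiver-public key pair, and write the payload file.

Receiver side (:func:`secure_predict`): decrypt the payload, run the
cleaning pipeline (dedup, impute, normalize), reduce with GK-LDA, then
train the EHGA-DLNN classifier or predict with a previously trained one,
and report confusion-matrix metrics when labels are present.

Because the encryption layer is lossless, the encrypted path and a
plaintext path over the same table produce bit-identical feature matrices
and identical predictions — :func:`run_pipeline` exposes both for that
equivalence check, and all randomness derives from one global seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import ehga, gklda, lrecc
from .auth import CredentialStore
from .ec import CURVES, KeyPair, generate_keypair
from .errors import AuthorizationError, ValidationError
from .metrics import ClassificationReport, classification_report
from .preprocess import FeatureMatrix, preprocess_table
from .synth import RawTable, table_from_csv, table_to_csv

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "secure_upload",
    "secure_predict",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run; round-trips losslessly via YAML."""

    curve: str = "secp256r1"
    cipher_shift: int = 3
    preprocess: bool = True
    gklda_mode: str = "kernel"
    gklda_gamma: Any = "median-heuristic"
    gklda_regularization: float | None = None
    n_components: int | None = None
    hidden_layers: tuple[int, ...] = (16,)
    n_clans: int = 10
    clan_size: int = 10
    max_iterations: int = 100
    loss_threshold: float = 0.0
    mutation_rate: float = 0.1
    seed: int = 0

    def to_yaml(self) -> str:
        data = dict(self.__dict__)
        data["hidden_layers"] = list(self.hidden_layers)
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        if "hidden_layers" in data:
            data["hidden_layers"] = tuple(data["hidden_layers"])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text(encoding="utf-8"))

    def train_config(self) -> ehga.TrainConfig:
        return ehga.TrainConfig(
            n_clans=self.n_clans,
            clan_size=self.clan_size,
            max_iterations=self.max_iterations,
            loss_threshold=self.loss_threshold,
            mutation_rate=self.mutation_rate,
            seed=self.seed,
        )


@dataclass
class PipelineResult:
    """Everything the receiver side produced in one run."""

    feature_matrix: FeatureMatrix
    reduced: np.ndarray
    basis: gklda.ProjectionBasis
    model: ehga.TrainedModel | None
    predictions: np.ndarray
    report: ClassificationReport | None
    log: list[str] = field(default_factory=list)


def secure_upload(
    table: RawTable,
    sender: KeyPair,
    receiver_public,
    config: PipelineConfig,
    rng: random.Random,
    *,
    credentials: tuple[CredentialStore, str, str, str] | None = None,
) -> lrecc.EncryptedPayload:
    """Encrypt a serialized patient table for the receiver.

    ``credentials`` is (store, username, password, token); when given, the
    upload aborts with :class:`AuthorizationError` unless the login
    verifies.
    """
    if credentials is not None:
        store, username, password, token = credentials
        decision = store.verify(username, password, token)
        if not decision.authorized:
            raise AuthorizationError(f"upload refused: {decision.reason}")
    curve = CURVES[config.curve]
    if sender.curve_id != curve.name:
        raise ValidationError("sender key pair is on a different curve")
    data = table_to_csv(table).encode("utf-8")
    return lrecc.encrypt(data, sender.private_scalar, receiver_public, curve, rng)


def _receiver_features(
    table: RawTable,
    config: PipelineConfig,
    bounds=None,
) -> FeatureMatrix:
    if config.preprocess:
        return preprocess_table(table, bounds=bounds)
    from .preprocess import to_matrix

    return to_matrix(table)


def secure_predict(
    payload: lrecc.EncryptedPayload,
    receiver: KeyPair,
    sender_public,
    config: PipelineConfig,
    *,
    model: ehga.TrainedModel | None = None,
    basis: gklda.ProjectionBasis | None = None,
    bounds=None,
) -> PipelineResult:
    """Decrypt, clean, reduce, and train (or apply) the classifier.

    Without ``model`` the run is a training run: a GK-LDA basis is fitted
    and the classifier trained on the decrypted table.  With ``model`` (and
    ``basis``/``bounds`` from the training run) it is a prediction run on
    new data.
    """
    curve = CURVES[config.curve]
    log: list[str] = []
    data = lrecc.decrypt(payload, receiver.private_scalar, sender_public, curve)
    table = table_from_csv(data.decode("utf-8"))
    log.append(f"decrypt: {len(payload.masked_points)} blocks -> {table.n_rows} rows")

    matrix = _receiver_features(table, config, bounds=bounds)
    log.append(
        f"preprocess: {table.n_rows} rows in -> {matrix.n_rows} rows, "
        f"{matrix.n_attributes} attributes"
    )

    if basis is None:
        basis = gklda.solve_discriminant(
            matrix.values,
            matrix.labels,
            mode=config.gklda_mode,  # type: ignore[arg-type]
            gamma=config.gklda_gamma,
            regularization=config.gklda_regularization,
            n_components=config.n_components,
        )
        log.append(
            f"gklda: fitted {basis.mode} basis with {basis.n_components} "
            "component(s)"
        )
    reduced = gklda.project(matrix.values, basis)
    log.append(f"reduce: {matrix.n_attributes} -> {reduced.shape[1]} dims")

    if model is None:
        model = ehga.train(
            reduced,
            matrix.labels,
            config.train_config(),
            hidden_layers=config.hidden_layers,
        )
        log.append(
            f"train: {model.n_iterations} iterations, "
            f"final loss {model.best_fitness:.6f}"
        )
    predictions = ehga.predict(model, reduced)

    report: ClassificationReport | None = None
    if len(np.unique(matrix.labels)) >= 2:
        report = classification_report(matrix.labels, predictions)
        log.append(f"report: accuracy {report.accuracy:.4f}")

    return PipelineResult(
        feature_matrix=matrix,
        reduced=reduced,
        basis=basis,
        model=model,
        predictions=predictions,
        report=report,
        log=log,
    )


def run_pipeline(
    table: RawTable, config: PipelineConfig, *, encrypted: bool = True
) -> PipelineResult:
    """One self-contained end-to-end run from a raw table.

    Generates sender and receiver key pairs from the config seed, optionally
    routes the table through the encrypted channel, then runs the receiver
    side (training mode).  ``encrypted=False`` skips the crypto layer but
    runs the identical downstream path, for the equivalence check.
    """
    curve = CURVES[config.curve]
    rng = random.Random(config.seed)
    sender = generate_keypair(curve, rng)
    receiver = generate_keypair(curve, rng)
    if encrypted:
        payload = secure_upload(
            table, sender, receiver.public_point, config, rng
        )
        return secure_predict(payload, receiver, sender.public_point, config)
    # plaintext path: same downstream stages on the unencrypted table
    matrix = _receiver_features(table, config)
    basis = gklda.solve_discriminant(
        matrix.values,
        matrix.labels,
        mode=config.gklda_mode,  # type: ignore[arg-type]
        gamma=config.gklda_gamma,
        regularization=config.gklda_regularization,
        n_components=config.n_components,
    )
    reduced = gklda.project(matrix.values, basis)
    model = ehga.train(
        reduced,
        matrix.labels,
        config.train_config(),
        hidden_layers=config.hidden_layers,
    )
    predictions = ehga.predict(model, reduced)
    report = None
    if len(np.unique(matrix.labels)) >= 2:
        report = classification_report(matrix.labels, predictions)
    return PipelineResult(
        feature_matrix=matrix,
        reduced=reduced,
        basis=basis,
        model=model,
        predictions=predictions,
        report=report,
        log=["plaintext path"],
    )
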