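"""Streaming seizure inference with simulated alert dispatch.

Each incoming epoch is standardized with the stored training statistics and
classified; a trigger policy ``(k, m)`` raises an alert at the first epoch
where at least k of the trailing m predictions are seizure-positive (default
``(1, 1)``: alert on every positive prediction), and no duplicate alert fires
until the window clears. Dispatch fans out to a notifier (dry-run log or an
SMTP client) and toggles named actuators; notifier failures never block
actuation (fail-open).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np

from .normalize import NormStats, apply_stats
from .types import EpochSet

__all__ = [
    "StreamPrediction",
    "AlertEvent",
    "AlertConfig",
    "ActuatorPanel",
    "DryRunNotifier",
    "SMTPNotifier",
    "stream_predict",
    "trigger",
    "dispatch",
    "run_alert_pipeline",
]


@dataclass(frozen=True)
class StreamPrediction:
    """One epoch's outcome in the stream (``error`` set on bad input)."""

    index: int
    label: int | None
    probability: float | None
    error: str | None = None


@dataclass
class AlertEvent:
    """A raised alarm: when, which epoch, what was predicted."""

    timestamp: str
    epoch_index: int
    label: int
    probability: float
    triggered_actions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        if self.label == 0:
            raise ValueError("seizure alerts require a non-zero label")


@dataclass
class AlertConfig:
    """Notifier choice, SMTP settings, actuators, and the trigger policy."""

    notifier: str = "dry_run"
    smtp_host: str = "localhost"
    smtp_port: int = 25
    smtp_credentials_env: str | None = None  # env-var name, never a secret
    recipient: str = ""
    actuators: list[str] = field(default_factory=lambda: ["fan", "light"])
    policy: tuple[int, int] = (1, 1)
    log_path: str | Path = "alerts.log"

    def __post_init__(self) -> None:
        k, m = self.policy
        if not 1 <= k <= m:
            raise ValueError("policy requires 1 <= k <= m")
        if self.notifier not in ("dry_run", "smtp"):
            raise ValueError(f"unknown notifier {self.notifier!r}")


class ActuatorPanel:
    """Named on/off switches with an optional JSON state file (no GPIO)."""

    def __init__(self, names: Iterable[str], state_path: str | Path | None = None) -> None:
        self.states: dict[str, bool] = {name: False for name in names}
        self.state_path = Path(state_path) if state_path else None

    def set_on(self, name: str) -> bool:
        """Switch ON; idempotent. Returns the (always-ON) new state."""
        self.states[name] = True
        self._persist()
        return True

    def set_off(self, name: str) -> bool:
        self.states[name] = False
        self._persist()
        return False

    def _persist(self) -> None:
        if self.state_path is not None:
            self.state_path.write_text(json.dumps(self.states, indent=2))


class DryRunNotifier:
    """Appends one structured JSON record per alert to a log file."""

    def __init__(self, log_path: str | Path) -> None:
        self.log_path = Path(log_path)

    def send(self, alert: AlertEvent) -> dict:
        record = {
            "timestamp": alert.timestamp,
            "epoch_index": alert.epoch_index,
            "label": alert.label,
            "probability": alert.probability,
            "notifier": "dry_run",
        }
        with open(self.log_path, "a") as fh:
            fh.write(json.dumps(record) + "\n")
        return record


class SMTPNotifier:
    """Composes an alert e-mail and hands it to a mail-transfer client.

    ``client_factory`` is injectable (tests pass a stub); the default uses
    :mod:`smtplib`. Credentials are read from the environment variable named
    in the config, never stored.
    """

    def __init__(self, cfg: AlertConfig, client_factory: Callable | None = None) -> None:
        self.cfg = cfg
        self.client_factory = client_factory

    def _default_factory(self):
        import smtplib

        return smtplib.SMTP(self.cfg.smtp_host, self.cfg.smtp_port, timeout=10)

    def send(self, alert: AlertEvent) -> dict:
        subject = f"Seizure alert: epoch {alert.epoch_index}"
        body = (
            f"Predicted label {alert.label} with probability "
            f"{alert.probability:.3f} at {alert.timestamp}."
        )
        factory = self.client_factory or self._default_factory
        client = factory()
        message = f"Subject: {subject}\nTo: {self.cfg.recipient}\n\n{body}"
        client.sendmail("seizurekit@localhost", self.cfg.recipient, message)
        return {
            "timestamp": alert.timestamp,
            "epoch_index": alert.epoch_index,
            "subject": subject,
            "recipient": self.cfg.recipient,
            "notifier": "smtp",
        }


def stream_predict(
    model,
    stats: NormStats,
    epoch_stream: Iterable[np.ndarray],
    threshold: float = 0.5,
) -> Iterator[StreamPrediction]:
    """Standardize and classify each epoch in order; bad epochs yield an
    error record and the stream continues."""
    from .models import predict

    spec = model.spec
    c, t = spec.input_shape
    for index, epoch in enumerate(epoch_stream):
        epoch = np.asarray(epoch, dtype=float)
        if epoch.shape != (c, t):
            yield StreamPrediction(index, None, None, f"expected shape {(c, t)}, got {epoch.shape}")
            continue
        es = EpochSet(epoch[None], np.zeros(1, dtype=np.int64), sfreq=t)
        std = apply_stats(es, stats)
        labels, probs = predict(model, std, threshold=threshold)
        prob = float(probs[0]) if probs.ndim == 1 else float(probs[0].max())
        yield StreamPrediction(index, int(labels[0]), prob)


def trigger(
    predictions: Iterable[StreamPrediction],
    policy: tuple[int, int] = (1, 1),
) -> list[AlertEvent]:
    """Raise alerts under the (k, m) trailing-window policy.

    An alert fires at the first epoch where >= k of the last m predictions
    are seizure-positive; the trigger then disarms until the window drops
    below k positives again (no duplicate alerts while it stays saturated).
    """
    k, m = policy
    if not 1 <= k <= m:
        raise ValueError("policy requires 1 <= k <= m")
    window: list[int] = []
    armed = True
    alerts: list[AlertEvent] = []
    for pred in predictions:
        positive = int(pred.label is not None and pred.label != 0)
        window.append(positive)
        if len(window) > m:
            window.pop(0)
        if sum(window) >= k:
            if armed:
                alerts.append(
                    AlertEvent(
                        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
                        epoch_index=pred.index,
                        label=pred.label if pred.label else 1,
                        probability=pred.probability if pred.probability is not None else 1.0,
                    )
                )
                armed = False
        else:
            armed = True
    return alerts


def dispatch(
    alert: AlertEvent,
    cfg: AlertConfig,
    panel: ActuatorPanel | None = None,
    notifier=None,
) -> dict:
    """Send one notification and switch every configured actuator ON.

    Exactly one delivery per call; notifier failures are recorded but never
    prevent actuation (fail-open for patient safety).
    """
    if panel is None:
        panel = ActuatorPanel(cfg.actuators)
    if notifier is None:
        notifier = DryRunNotifier(cfg.log_path) if cfg.notifier == "dry_run" else SMTPNotifier(cfg)
    record: dict = {"epoch_index": alert.epoch_index, "notified": False, "error": None}
    try:
        delivery = notifier.send(alert)
        record.update(delivery)
        record["notified"] = True
    except Exception as exc:  # fail-open: actuators must still fire
        record["error"] = str(exc)
    for name in cfg.actuators:
        panel.set_on(name)
        alert.triggered_actions.append(f"{name}:ON")
    record["actuators"] = dict(panel.states)
    return record


def run_alert_pipeline(
    model,
    stats: NormStats,
    epochs: np.ndarray,
    cfg: AlertConfig,
    panel: ActuatorPanel | None = None,
    notifier=None,
) -> tuple[list[AlertEvent], list[dict]]:
    """Stream epochs through the model, trigger, and dispatch each alert once."""
    predictions = list(stream_predict(model, stats, epochs))
    alerts = trigger(predictions, cfg.policy)
    if panel is None:
        panel = ActuatorPanel(cfg.actuators)
    records = [dispatch(alert, cfg, panel=panel, notifier=notifier) for alert in alerts]
    return alerts, records
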