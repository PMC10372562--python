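"""Star-topology workflow engine.

Simulates the execution of a chained federated workflow among one
coordinator and N participants, entirely in process.  Apps are round-driven
state machines: each round every participant computes an outbound payload
from its local state and the last broadcast, the coordinator aggregates the
gathered payloads, and either broadcasts the next round's input or signals
completion.  The engine owns the only communication channel — an in-memory
message bus with byte-size accounting — so the communication pattern the
topology promises is enforced structurally:

* participants talk to the coordinator only (the single exception is
  relayed secret shares, which the coordinator forwards blindly);
* aggregated results are broadcast to every participant;
* raw feature/label arrays never enter a message (auditable through the
  payload-kind whitelist over the full log).

Aggregation is barrier-synchronized: the coordinator waits for every
participant before aggregating, which makes runs deterministic and — for
the sum-based aggregators used throughout — result-identical to any
eager schedule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np

from . import secure_agg
from .secure_agg import FixedPointCodec, ProtocolError
from .synth import PartyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "BROADCAST",
    "ConfigError",
    "RoleViolation",
    "GatherTimeout",
    "WorkflowError",
    "PartyRole",
    "Message",
    "WorkflowStep",
    "WorkflowConfig",
    "WorkflowResult",
    "MessageBus",
    "Summable",
    "Opaque",
    "FederatedApp",
    "register_app",
    "run_workflow",
]

#: Recipient id meaning "every participant".
BROADCAST = -1

#: Every payload kind that may legally appear in the message log.  Raw
#: feature matrices / label vectors have no kind, so their absence is
#: auditable: any unlisted kind fails the audit.
PAYLOAD_KIND_WHITELIST = {
    "ack",
    "sample_count",
    "moments",
    "gram",
    "newton_stats",
    "trees",
    "weighted_params",
    "confusion",
    "error_sums",
    "event_table",
    "local_metric",
    "category_set",
    "broadcast",
    "secret_share",
    "secure_partial",
    "final_result",
}


class ConfigError(ValueError):
    """Invalid workflow configuration (unknown app, broken slot chain...)."""


class RoleViolation(RuntimeError):
    """A party attempted an operation its role does not allow."""


class GatherTimeout(RuntimeError):
    """A participant failed to submit for a round."""


class WorkflowError(RuntimeError):
    """An app failed mid-run; carries the failing step for rerun support."""

    def __init__(self, step_index: int, app_name: str, cause: Exception):
        self.step_index = step_index
        self.app_name = app_name
        self.cause = cause
        super().__init__(
            f"workflow aborted at step {step_index} ({app_name}): {cause!r}"
        )


class RoleKind(str, Enum):
    PARTICIPANT = "participant"
    COORDINATOR = "coordinator"


@dataclass(frozen=True)
class PartyRole:
    kind: RoleKind
    party_id: int


def payload_nbytes(obj: Any) -> int:
    """Serialized size: 8 bytes per numeric-array element (little-endian
    float64 block), canonical JSON for everything else."""
    if isinstance(obj, np.ndarray):
        return int(obj.size) * 8
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return len(json.dumps(obj))
    if isinstance(obj, (list, tuple)):
        return 2 + sum(payload_nbytes(x) + 1 for x in obj)
    if isinstance(obj, dict):
        return 2 + sum(
            len(json.dumps(str(k))) + 1 + payload_nbytes(v)
            for k, v in obj.items()
        )
    if hasattr(obj, "as_vector"):
        return payload_nbytes(obj.as_vector())
    return len(json.dumps(obj, default=str, sort_keys=True))


@dataclass
class Message:
    sender: int
    recipient: int  # party id or BROADCAST
    round: int
    payload_kind: str
    byte_size: int
    step_index: int = -1


@dataclass
class MessageBus:
    """Ordered message log plus the two communication primitives.

    Payload contents are retained (keyed by log position) so tests can
    audit them, but the log entries themselves carry only metadata.
    """

    coordinator_id: int
    n_participants: int
    log: list[Message] = field(default_factory=list)
    payloads: dict[int, Any] = field(default_factory=dict)
    _inbox: dict[tuple[int, str], dict[int, Any]] = field(
        default_factory=dict
    )
    step_index: int = -1

    def send(
        self,
        sender: int,
        recipient: int,
        round: int,
        payload_kind: str,
        payload: Any,
    ) -> None:
        if payload_kind not in PAYLOAD_KIND_WHITELIST:
            raise ProtocolError(
                f"payload kind {payload_kind!r} is not whitelisted"
            )
        if (
            sender != self.coordinator_id
            and recipient != self.coordinator_id
            and payload_kind != "secret_share"
        ):
            raise RoleViolation(
                "participant-to-participant traffic is forbidden except "
                "for relayed secret shares"
            )
        msg = Message(
            sender=sender,
            recipient=recipient,
            round=round,
            payload_kind=payload_kind,
            byte_size=payload_nbytes(payload),
            step_index=self.step_index,
        )
        self.payloads[len(self.log)] = payload
        self.log.append(msg)
        if recipient == self.coordinator_id:
            self._inbox.setdefault((round, payload_kind), {})[sender] = (
                payload
            )

    def gather(self, round: int, payload_kind: str) -> list[Any]:
        """Coordinator-side barrier: one payload per participant, ordered
        by party id; a missing submission is a timeout naming the party."""
        box = self._inbox.get((round, payload_kind), {})
        expected = set(range(self.n_participants))
        missing = sorted(expected - set(box))
        if missing:
            raise GatherTimeout(
                f"round {round}: no {payload_kind!r} submission from "
                f"part{'ies' if len(missing) > 1 else 'y'} {missing}"
            )
        return [box[i] for i in sorted(box)]

    def broadcast(
        self, sender: int, round: int, payload_kind: str, payload: Any
    ) -> None:
        """One identical message per participant; coordinator only."""
        if sender != self.coordinator_id:
            raise RoleViolation(
                f"party {sender} attempted a broadcast; only the "
                f"coordinator (id {self.coordinator_id}) may broadcast"
            )
        for pid in range(self.n_participants):
            self.send(sender, pid, round, payload_kind, payload)

    def traffic_summary(self) -> dict:
        by_kind: dict[str, dict[str, int]] = {}
        for m in self.log:
            e = by_kind.setdefault(
                m.payload_kind, {"messages": 0, "bytes": 0}
            )
            e["messages"] += 1
            e["bytes"] += m.byte_size
        return {
            "total_messages": len(self.log),
            "total_bytes": sum(m.byte_size for m in self.log),
            "by_kind": by_kind,
        }


def audit_log(messages: list[Message]) -> None:
    """Privacy-pattern audit: every payload kind whitelisted; no raw-data
    kinds exist, so raw arrays cannot have crossed a silo boundary."""
    for m in messages:
        if m.payload_kind not in PAYLOAD_KIND_WHITELIST:
            raise ProtocolError(
                f"non-whitelisted payload kind {m.payload_kind!r} in log"
            )


# ---------------------------------------------------------------------------
# Payload wrappers and the app interface
# ---------------------------------------------------------------------------


@dataclass
class Summable:
    """A numeric vector the coordinator only needs the *sum* of.

    With secure aggregation enabled these are exchanged as additive secret
    shares; the coordinator then sees only the global sum either way.
    """

    vector: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()


@dataclass
class Opaque:
    """A payload gathered as-is (per-party list at the coordinator)."""

    value: Any
    kind: str


@dataclass
class Gathered:
    """What the coordinator phase receives for one round."""

    round: int
    sums: dict[str, np.ndarray] = field(default_factory=dict)
    items: dict[str, list[Any]] = field(default_factory=dict)


@dataclass
class PartyState:
    """One party's private workspace; never serialized into messages."""

    party_id: int
    dataset: PartyDataset | None
    slots: dict[str, Any] = field(default_factory=dict)
    local: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


class FederatedApp:
    """Base class for registry apps.

    Subclasses are instantiated once per workflow step and may keep
    coordinator-side state across rounds (fold index, current
    coefficients...).  ``participant_phase`` must touch only the given
    party's state.
    """

    name: str = "abstract"

    def initial_broadcast(self, params: dict, n_parties: int) -> Any:
        return None

    def participant_phase(
        self,
        state: PartyState,
        broadcast_in: Any,
        params: dict,
        round_idx: int,
    ) -> dict[str, Summable | Opaque]:
        raise NotImplementedError

    def coordinator_phase(
        self, gathered: Gathered, params: dict, n_parties: int
    ) -> tuple[Any, bool]:
        """Return (broadcast payload, done flag)."""
        raise NotImplementedError

    def finalize_party(
        self, state: PartyState, final_broadcast: Any, params: dict
    ) -> Any:
        """Build the party's local output for the produced slot."""
        return None

    def report(self) -> dict:
        """Coordinator-side per-step summary."""
        return {}


_APP_REGISTRY: dict[str, type[FederatedApp]] = {}


def register_app(cls: type[FederatedApp]) -> type[FederatedApp]:
    _APP_REGISTRY[cls.name] = cls
    return cls


def registered_apps() -> list[str]:
    return sorted(_APP_REGISTRY)


# ---------------------------------------------------------------------------
# Workflow configuration and execution
# ---------------------------------------------------------------------------


@dataclass
class WorkflowStep:
    app_name: str
    params: dict = field(default_factory=dict)
    consumes: str = ""
    produces: str = ""


@dataclass
class WorkflowConfig:
    steps: list[WorkflowStep]
    n_parties: int
    seed: int = 0
    coordinator_has_data: bool = True
    secure_aggregation: bool = False
    max_rounds_per_step: int = 10_000

    def validate(self) -> None:
        if not self.steps:
            raise ConfigError("workflow has no steps")
        for s in self.steps:
            if s.app_name not in _APP_REGISTRY:
                raise ConfigError(
                    f"unknown app {s.app_name!r}; registered: "
                    f"{registered_apps()}"
                )
        # auto-chain slots when unspecified, then check consistency
        prev = "data"
        for i, s in enumerate(self.steps):
            if not s.consumes:
                s.consumes = prev
            elif s.consumes != prev:
                raise ConfigError(
                    f"step {i} ({s.app_name}) consumes {s.consumes!r} but "
                    f"the previous step produced {prev!r}"
                )
            if not s.produces:
                s.produces = f"slot{i + 1}"
            prev = s.produces


@dataclass
class WorkflowResult:
    final_outputs: dict[int, Any]
    message_log: list[Message]
    per_step_reports: list[dict]
    traffic: dict
    bus: MessageBus


def _secure_sum_round(
    bus: MessageBus,
    vectors: list[np.ndarray],
    round: int,
    codec: FixedPointCodec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Full share choreography with per-message logging.

    Each party splits its vector into N shares and sends one to every peer
    (relayed via the coordinator, which cannot decode a single share);
    each party then sums what it received and submits only the partial sum.
    """
    n = len(vectors)
    bundles = [
        secure_agg.make_shares(v, n, codec, rng) for v in vectors
    ]
    for i, bundle in enumerate(bundles):
        for j in range(n):
            if j == i:
                continue  # own share kept locally
            bus.send(i, j, round, "secret_share", bundle.shares[j])
    partials = []
    for j in range(n):
        received = [bundles[i].shares[j] for i in range(n)]
        partial = secure_agg.combine_received(received, codec.modulus)
        bus.send(j, bus.coordinator_id, round, "secure_partial", partial)
        partials.append(partial)
    return secure_agg.reconstruct_sum(partials, codec, n_parties=n)


def run_workflow(
    config: WorkflowConfig, datasets: list[PartyDataset]
) -> WorkflowResult:
    """Execute a chained workflow over the given per-party datasets.

    Each step runs its participant phase at every party and its
    coordinator aggregation per round until the app signals completion;
    the produced per-party outputs stay in local slot stores and never
    appear in messages.  The final step's result is broadcast to all
    parties.
    """
    config.validate()
    if len(datasets) < 1:
        raise ConfigError("need at least one party dataset")
    if len(datasets) != config.n_parties:
        raise ConfigError(
            f"config names {config.n_parties} parties but "
            f"{len(datasets)} datasets were supplied"
        )

    n = config.n_parties
    # Coordinator doubles as participant 0 by default; otherwise it is an
    # extra, data-free party with the next free id.
    coordinator_id = 0 if config.coordinator_has_data else n
    bus = MessageBus(coordinator_id=coordinator_id, n_participants=n)

    seed_root = np.random.SeedSequence(config.seed)
    party_seeds = [int(s.generate_state(1)[0] % 2**31) for s in seed_root.spawn(n)]
    states = [
        PartyState(
            party_id=i,
            dataset=datasets[i],
            slots={"data": datasets[i]},
            seed=party_seeds[i],
        )
        for i in range(n)
    ]
    secure_rng = np.random.default_rng(
        int(seed_root.generate_state(2)[1] % 2**31)
    )
    codec = FixedPointCodec()

    reports: list[dict] = []
    final_broadcast: Any = None
    for step_index, step in enumerate(config.steps):
        bus.step_index = step_index
        app = _APP_REGISTRY[step.app_name]()
        params = dict(step.params)
        params["_consumes"] = step.consumes
        secure = params.get(
            "secure_aggregation", config.secure_aggregation
        )
        try:
            broadcast_in = app.initial_broadcast(params, n)
            if broadcast_in is not None:
                bus.broadcast(coordinator_id, 0, "broadcast", broadcast_in)
            done = False
            round = 0
            while not done:
                if round > config.max_rounds_per_step:
                    raise RuntimeError(
                        f"app exceeded {config.max_rounds_per_step} rounds"
                    )
                outputs = [
                    app.participant_phase(
                        states[i], broadcast_in, params, round
                    )
                    for i in range(n)
                ]
                gathered = Gathered(round=round)
                names = list(outputs[0].keys())
                for name in names:
                    payloads = [out[name] for out in outputs]
                    if isinstance(payloads[0], Summable):
                        if secure:
                            if n < secure_agg.MIN_PARTIES:
                                raise ProtocolError(
                                    "secure aggregation requires >= 3 "
                                    f"parties, workflow has {n}"
                                )
                            gathered.sums[name] = _secure_sum_round(
                                bus,
                                [p.vector for p in payloads],
                                round,
                                codec,
                                secure_rng,
                            )
                        else:
                            for i, p in enumerate(payloads):
                                bus.send(
                                    i, coordinator_id, round,
                                    p.kind, p.vector,
                                )
                            gathered.sums[name] = np.sum(
                                [p.vector for p in payloads], axis=0
                            )
                            gathered.items[name] = [
                                p.vector for p in payloads
                            ]
                    else:
                        for i, p in enumerate(payloads):
                            bus.send(
                                i, coordinator_id, round, p.kind, p.value
                            )
                        gathered.items[name] = [p.value for p in payloads]
                broadcast_out, done = app.coordinator_phase(
                    gathered, params, n
                )
                if broadcast_out is not None:
                    bus.broadcast(
                        coordinator_id, round + 1, "broadcast",
                        broadcast_out,
                    )
                broadcast_in = broadcast_out
                round += 1
            for state in states:
                produced = app.finalize_party(state, broadcast_in, params)
                state.slots[step.produces] = produced
            reports.append(
                {"app": step.app_name, "step": step_index, **app.report()}
            )
            final_broadcast = broadcast_in
        except (ConfigError, ProtocolError, RoleViolation):
            raise
        except Exception as exc:  # noqa: BLE001 — abort with step identity
            raise WorkflowError(step_index, step.app_name, exc) from exc

    # final results are shared with every participant
    bus.step_index = len(config.steps)
    bus.broadcast(
        coordinator_id,
        len(bus.log),
        "final_result",
        {"report": reports[-1] if reports else {}},
    )
    final_slot = config.steps[-1].produces
    return WorkflowResult(
        final_outputs={s.party_id: s.slots.get(final_slot) for s in states},
        message_log=bus.log,
        per_step_reports=reports,
        traffic=bus.traffic_summary(),
        bus=bus,
    )
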