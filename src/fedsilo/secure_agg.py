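"""Additive secret sharing for secure summation.

Each party splits its real-valued vector into N random residue vectors
("shares") over a prime ring; shares are exchanged so that every party ends
up holding one share from each peer.  Each party sums the shares it received
and forwards only that partial sum to the coordinator, who adds the partials
and decodes.  The coordinator therefore learns the global sum, never any
party's local vector.

Real values are mapped into the ring by a fixed-point encoding: multiply by
a power-of-ten scale, round, reduce modulo a 62-bit prime.  Signed values
are centred at half the modulus on decode.  The scheme supports exactly the
two operations additive sharing admits: addition of secrets and
multiplication by public constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_MODULUS",
    "DEFAULT_SCALE",
    "FixedPointCodec",
    "ProtocolError",
    "EncodingError",
    "ShareBundle",
    "make_shares",
    "combine_received",
    "reconstruct_sum",
    "secure_sum_traffic",
]

#: 62-bit prime ring modulus: the smallest prime above 2**61.
DEFAULT_MODULUS = 2305843009213693967

#: Fixed-point scale: six decimal digits of fractional precision.
DEFAULT_SCALE = 10**6

MIN_PARTIES = 3


class ProtocolError(RuntimeError):
    """Violation of the sharing protocol (too few parties, bad shapes...)."""


class EncodingError(ValueError):
    """A value does not fit in the fixed-point ring."""


@dataclass(frozen=True)
class FixedPointCodec:
    """Signed fixed-point encoding into the residue ring Z_modulus.

    Parameters
    ----------
    scale:
        Power-of-ten multiplier; ``1/scale`` is the quantisation step.
    modulus:
        Prime ring size.  Residues above ``modulus // 2`` decode negative.
    """

    scale: int = DEFAULT_SCALE
    modulus: int = DEFAULT_MODULUS

    def encode(self, values: np.ndarray) -> np.ndarray:
        """Map a real vector to residues; rejects magnitudes ≥ modulus/2."""
        values = np.asarray(values, dtype=float)
        scaled = np.rint(values * self.scale)
        if not np.all(np.isfinite(scaled)):
            raise EncodingError("non-finite value cannot be encoded")
        if np.any(np.abs(scaled) >= self.modulus // 2):
            raise EncodingError(
                f"magnitude overflow: |value|*{self.scale} must stay below "
                f"modulus/2 = {self.modulus // 2}"
            )
        return np.array(
            [int(s) % self.modulus for s in scaled.ravel()], dtype=object
        ).reshape(scaled.shape)

    def decode(self, residues: np.ndarray) -> np.ndarray:
        """Map residues back to reals, centring the sign at modulus/2."""
        half = self.modulus // 2
        out = np.empty(np.shape(residues), dtype=float)
        flat_in = np.asarray(residues, dtype=object).ravel()
        flat_out = out.ravel()
        for i, r in enumerate(flat_in):
            r = int(r) % self.modulus
            signed = r - self.modulus if r > half else r
            flat_out[i] = signed / self.scale
        return out


@dataclass
class ShareBundle:
    """The N residue vectors one party produced for its secret.

    ``shares[j]`` is destined for party ``j`` (including one the owner keeps
    for itself).  Their elementwise modular sum equals the encoded secret.
    """

    owner: int
    shares: list[np.ndarray]
    length: int
    codec: FixedPointCodec = field(default_factory=FixedPointCodec)


def _mod_add(a: np.ndarray, b: np.ndarray, modulus: int) -> np.ndarray:
    out = np.empty(len(a), dtype=object)
    for i in range(len(a)):
        out[i] = (int(a[i]) + int(b[i])) % modulus
    return out


def make_shares(
    secret: np.ndarray,
    n_parties: int,
    codec: FixedPointCodec | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> ShareBundle:
    """Split a real vector into ``n_parties`` additive shares.

    The first N−1 shares are uniform over the ring; the last is the encoded
    secret minus their sum, so the modular total reconstructs the secret.
    Below three parties the scheme offers no protection (the coordinator
    could subtract its own contribution and recover the other party's
    vector), so ``n_parties < 3`` is a protocol error.
    """
    if n_parties < MIN_PARTIES:
        raise ProtocolError(
            f"additive secret sharing requires >= {MIN_PARTIES} parties, "
            f"got {n_parties}"
        )
    codec = codec or FixedPointCodec()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    secret = np.asarray(secret, dtype=float).ravel()
    encoded = codec.encode(secret)
    length = len(secret)

    shares: list[np.ndarray] = []
    running = np.zeros(length, dtype=object)
    for _ in range(n_parties - 1):
        draw = rng.integers(0, codec.modulus, size=length, dtype=np.uint64)
        draw_obj = np.array([int(d) for d in draw], dtype=object)
        shares.append(draw_obj)
        running = _mod_add(running, draw_obj, codec.modulus)
    last = np.empty(length, dtype=object)
    for i in range(length):
        last[i] = (int(encoded[i]) - int(running[i])) % codec.modulus
    shares.append(last)
    return ShareBundle(owner=-1, shares=shares, length=length, codec=codec)


def combine_received(
    received_shares: list[np.ndarray],
    modulus: int = DEFAULT_MODULUS,
) -> np.ndarray:
    """Elementwise modular sum of the shares addressed to one party."""
    if not received_shares:
        raise ProtocolError("no shares to combine")
    lengths = {len(s) for s in received_shares}
    if len(lengths) != 1:
        raise ProtocolError(f"share length mismatch: {sorted(lengths)}")
    total = np.zeros(lengths.pop(), dtype=object)
    for s in received_shares:
        total = _mod_add(total, np.asarray(s, dtype=object), modulus)
    return total


def reconstruct_sum(
    partials: list[np.ndarray],
    codec: FixedPointCodec | None = None,
    n_parties: int | None = None,
) -> np.ndarray:
    """Decode the global sum from the per-party partial sums.

    With one partial per party the modular total telescopes to the sum of
    all encoded secrets; decoding recovers the real-valued global sum up to
    one quantisation step (1/scale) per summand.
    """
    codec = codec or FixedPointCodec()
    if n_parties is not None and len(partials) != n_parties:
        missing = n_parties - len(partials)
        raise ProtocolError(f"missing {missing} partial sum(s)")
    total = combine_received(partials, codec.modulus)
    return codec.decode(total)


def secure_sum_traffic(n_parties: int, vector_len: int) -> dict[str, int]:
    """Share-exchange message and byte counts for one secure summation.

    Every party sends one share to each of the other N−1 parties, hence
    N·(N−1) share messages — the quadratic growth in network traffic that is
    the protocol's main cost.  Bytes assume 8-byte residues.
    """
    if n_parties < MIN_PARTIES:
        raise ProtocolError(
            f"secure aggregation undefined below {MIN_PARTIES} parties"
        )
    n_messages = n_parties * (n_parties - 1)
    return {
        "share_messages": n_messages,
        "share_bytes": n_messages * vector_len * 8,
        "partial_messages": n_parties,
        "partial_bytes": n_parties * vector_len * 8,
    }


def secure_sum(
    secrets: list[np.ndarray],
    codec: FixedPointCodec | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """End-to-end secure summation of one vector per party (convenience).

    Runs the full choreography in one process: share, exchange, combine,
    reconstruct.  The engine replays the same steps message by message.
    """
    codec = codec or FixedPointCodec()
    n = len(secrets)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    bundles = [make_shares(s, n, codec, rng) for s in secrets]
    partials = [
        combine_received([b.shares[j] for b in bundles], codec.modulus)
        for j in range(n)
    ]
    return reconstruct_sum(partials, codec, n_parties=n)
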