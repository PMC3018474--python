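"""Two-state (Ising-type) model of DNA duplex instability.

Each base pair i of a duplex of length N carries a spin sigma_i in {0, 1}
(closed / open).  A configuration's Boltzmann weight is

    prod_{i=1..N} (delta_i * alpha_i)^sigma_i * (delta_{i+1} * xi)^f(sigma_i, sigma_{i+1})

with boundary conditions delta_1 = delta_{N+1} = 1 and sigma_{N+1} = 1, where

* alpha_i = exp(dG_BP_i / RT) is the base-pairing weight of position i
  (AT or GC entry of the pairing table),
* delta_i = exp(dG_ST_{i-1,i} / RT) is the stacking weight of the
  dinucleotide step ending at i (read 5'->3' on the given strand),
* xi is the ring factor, an entropic penalty for the loop formed by a
  flipped-out base (1 by default, i.e. neglected),
* f(s, t) = s if t == 0 else 0 marks the right edge of an open run and
  charges it the stacking weight lost at that edge.

The partition function Z sums the weight over all 2^N configurations; the
conditional partition function Z_k(n) sums over configurations in which
base pairs n .. n+k-1 are forced open.  The opening propensity (bubble
probability) is P_k(n) = Z_k(n) / Z.

Z is a product of 2x2 transfer matrices, so Z and the whole profile
{P_k(n)}_n are computed in O(N) with log-scale rescaling; the exhaustive
enumerator :func:`brute_force_partition` is retained as the ground-truth
oracle for small N.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "NucleotideSequence",
    "ThermoParams",
    "SpinConfiguration",
    "OpeningProfile",
    "edge_indicator",
    "pairing_weight",
    "stacking_weight",
    "brute_force_partition",
    "transfer_partition",
    "opening_profile",
    "reverse_complement",
]

#: Gas constant in kcal/(mol*K); the free-energy tables are in kcal/mol.
GAS_CONSTANT_KCAL = 1.9872e-3

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Stacking free energies dG_ST[KL] in kcal/mol, K = base i-1, L = base i,
# read 5'->3' along the given strand.  The table is reverse-complement
# symmetric: dG[KL] == dG[comp(L)comp(K)].
DEFAULT_STACK_DG: dict[str, float] = {
    "AA": -1.49, "AT": -1.72, "AG": -1.44, "AC": -2.19,
    "TA": -0.57, "TT": -1.49, "TG": -0.93, "TC": -1.81,
    "GA": -1.81, "GT": -2.19, "GG": -1.82, "GC": -2.55,
    "CA": -0.93, "CT": -1.44, "CG": -1.29, "CC": -1.82,
}

#: Pairing free energies dG_BP in kcal/mol by pair type.
DEFAULT_PAIR_DG: dict[str, float] = {"AT": 0.64, "GC": 0.12}

#: Hard cap on N for the exhaustive enumerator (cost is 2^N).
BRUTE_FORCE_CAP = 20


def reverse_complement(bases: str) -> str:
    """Reverse complement of a strict A/C/G/T string."""
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideSequence:
    """A strict A/C/G/T sequence with 1-based indexing.

    Parameters
    ----------
    id : str
        Text label (FASTA header token).
    bases : str
        Uppercase string over {A, C, G, T}.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, b in enumerate(self.bases, start=1):
            if b not in _VALID_BASES:
                raise ValueError(
                    f"sequence {self.id!r}: invalid base {b!r} at position {pos} "
                    "(only A, C, G, T are allowed)"
                )

    @property
    def n(self) -> int:
        """Length N in base pairs."""
        return len(self.bases)

    def base(self, i: int) -> str:
        """Base at 1-based position i."""
        if not 1 <= i <= self.n:
            raise IndexError(f"position {i} outside [1, {self.n}]")
        return self.bases[i - 1]

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(f"{self.id}_rc", reverse_complement(self.bases))


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameters of the two-state duplex model.

    Attributes
    ----------
    stack_dg : dict
        16 stacking free energies dG_ST[KL], kcal/mol, KL a dinucleotide
        read 5'->3' (K = previous base, L = current base).
    pair_dg : dict
        Pairing free energies, kcal/mol, keys "AT" and "GC".
    temperature_celsius : float
        Temperature in degrees Celsius (default 37).
    gas_constant : float
        R in kcal/(mol*K).
    ring_factor : float
        Dimensionless entropic loop parameter xi > 0 (default 1).
    """

    stack_dg: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STACK_DG))
    pair_dg: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PAIR_DG))
    temperature_celsius: float = 37.0
    gas_constant: float = GAS_CONSTANT_KCAL
    ring_factor: float = 1.0

    def __post_init__(self) -> None:
        missing = {a + b for a in "ACGT" for b in "ACGT"} - set(self.stack_dg)
        if missing:
            raise ValueError(f"stacking table incomplete, missing {sorted(missing)}")
        if set(self.pair_dg) != {"AT", "GC"}:
            raise ValueError("pairing table must have exactly the keys 'AT' and 'GC'")
        if self.temperature_kelvin <= 0:
            raise ValueError("temperature below absolute zero")
        if self.ring_factor <= 0:
            raise ValueError("ring factor must be positive")
        if self.gas_constant <= 0:
            raise ValueError("gas constant must be positive")

    @property
    def temperature_kelvin(self) -> float:
        return self.temperature_celsius + 273.15

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature_kelvin

    def fingerprint(self) -> str:
        """Short stable identifier of the full parameter set."""
        payload = json.dumps(
            {
                "stack": {k: self.stack_dg[k] for k in sorted(self.stack_dg)},
                "pair": {k: self.pair_dg[k] for k in sorted(self.pair_dg)},
                "T_celsius": self.temperature_celsius,
                "R": self.gas_constant,
                "xi": self.ring_factor,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "stack_dg": dict(self.stack_dg),
            "pair_dg": dict(self.pair_dg),
            "temperature_celsius": self.temperature_celsius,
            "gas_constant": self.gas_constant,
            "ring_factor": self.ring_factor,
        }

    @classmethod
    def from_overrides(cls, overrides: dict | None = None) -> "ThermoParams":
        """Build params from a (possibly partial) JSON-style override mapping."""
        base = cls().to_dict()
        for key, val in (overrides or {}).items():
            if key not in base:
                raise KeyError(f"unknown parameter {key!r}")
            if isinstance(base[key], dict):
                base[key] = {**base[key], **val}
            else:
                base[key] = val
        return cls(**base)


def edge_indicator(sigma_i: int, sigma_next: int) -> int:
    """f(sigma_i, sigma_{i+1}): 1 only at the right edge of an open run."""
    return sigma_i if sigma_next == 0 else 0


@dataclass(frozen=True)
class SpinConfiguration:
    """One open/closed assignment over positions 1..N (sigma_{N+1} = 1 implicit)."""

    sigma: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s not in (0, 1) for s in self.sigma):
            raise ValueError("spins must be 0 or 1")

    def edge(self, i: int) -> int:
        """f(sigma_i, sigma_{i+1}) with the sigma_{N+1}=1 boundary."""
        n = len(self.sigma)
        s_next = 1 if i == n else self.sigma[i]  # sigma[i] is sigma_{i+1}, 0-based
        return edge_indicator(self.sigma[i - 1], s_next)


def pairing_weight(base: str, params: ThermoParams) -> float:
    """alpha = exp(dG_BP / RT) for one base (AT entry for A/T, GC for G/C)."""
    if base in "AT":
        dg = params.pair_dg["AT"]
    elif base in "GC":
        dg = params.pair_dg["GC"]
    else:
        raise ValueError(f"unknown base {base!r}")
    return math.exp(dg / params.rt)


def stacking_weight(i: int, seq: NucleotideSequence, params: ThermoParams) -> float:
    """delta_i = exp(dG_ST_{i-1,i} / RT); boundary delta_1 = delta_{N+1} = 1."""
    if not 1 <= i <= seq.n + 1:
        raise IndexError(f"stacking index {i} outside [1, {seq.n + 1}]")
    if i == 1 or i == seq.n + 1:
        return 1.0
    step = seq.bases[i - 2 : i]
    return math.exp(params.stack_dg[step] / params.rt)


def _weight_arrays(seq: NucleotideSequence, params: ThermoParams):
    """alpha[1..N] and delta[1..N+1] as float arrays (index 0 unused)."""
    n = seq.n
    rt = params.rt
    pair = {b: math.exp(params.pair_dg["AT" if b in "AT" else "GC"] / rt) for b in "ACGT"}
    alpha = np.empty(n + 1)
    alpha[0] = np.nan
    for i, b in enumerate(seq.bases, start=1):
        alpha[i] = pair[b]
    delta = np.ones(n + 2)
    stack = {kl: math.exp(dg / rt) for kl, dg in params.stack_dg.items()}
    for i in range(2, n + 1):
        delta[i] = stack[seq.bases[i - 2 : i]]
    return alpha, delta


class ScaledValue(NamedTuple):
    """A positive scalar as mantissa * exp(log_scale), safe far outside float range."""

    mantissa: float
    log_scale: float

    @property
    def log(self) -> float:
        return self.log_scale + math.log(self.mantissa)

    @property
    def value(self) -> float:
        return math.exp(self.log)


def brute_force_partition(
    seq: NucleotideSequence,
    params: ThermoParams | None = None,
    forced_open_window: tuple[int, int] | None = None,
) -> float:
    """Partition function by exhaustive enumeration of all 2^N configurations.

    With ``forced_open_window=(n, k)`` the spins at positions n..n+k-1 are
    fixed open and the conditional partition function Z_k(n) is returned.
    Ground-truth oracle for the linear-time path; cost 2^N, so N is capped
    at ``BRUTE_FORCE_CAP``.
    """
    params = params or ThermoParams()
    n_bp = seq.n
    if n_bp > BRUTE_FORCE_CAP:
        raise ValueError(
            f"N={n_bp} exceeds the exhaustive-enumeration cap {BRUTE_FORCE_CAP}; "
            "use opening_profile/transfer_partition (linear time) instead"
        )
    if forced_open_window is not None:
        n0, k = forced_open_window
        if not (1 <= n0 and k >= 1 and n0 + k - 1 <= n_bp):
            raise ValueError(f"forced window ({n0}, {k}) outside sequence of length {n_bp}")

    alpha, delta = _weight_arrays(seq, params)
    xi = params.ring_factor

    configs = np.arange(2**n_bp, dtype=np.int64)
    # sigma[c, i] for positions 1..N, plus the fixed sigma_{N+1} = 1 column
    sigma = (configs[:, None] >> np.arange(n_bp)) & 1
    sigma = np.concatenate([sigma, np.ones((len(configs), 1), dtype=sigma.dtype)], axis=1)

    if forced_open_window is not None:
        n0, k = forced_open_window
        keep = sigma[:, n0 - 1 : n0 + k - 1].all(axis=1)
        sigma = sigma[keep]

    a = alpha[1 : n_bp + 1]
    d = delta[1 : n_bp + 1]
    d_next = delta[2 : n_bp + 2]
    f = sigma[:, :-1] * (1 - sigma[:, 1:])  # f(s_i, s_{i+1})
    log_w = sigma[:, :-1] @ np.log(d * a) + f @ np.log(d_next * xi)
    return float(np.exp(log_w).sum())


def _prefix_suffix(seq: NucleotideSequence, params: ThermoParams):
    """Log-scaled boundary contractions of the transfer-matrix product.

    Returns (log_u1, log_v1, log_da_cumsum) where

    * log_u1[n]  = log of the summed weight of positions 1..n-1 with
      sigma_n = 1   (left prefix, n = 1..N+1),
    * log_v1[m]  = log of the summed weight of positions m..N with
      sigma_m = 1 and the sigma_{N+1}=1 boundary (right suffix, m = 1..N+1,
      where log_v1[N+1] := 0),
    * log_da_cumsum[j] = sum_{i<=j} log(delta_i * alpha_i), j = 0..N.

    All arrays are 1-based (index 0 unused where noted).
    """
    n = seq.n
    alpha, delta = _weight_arrays(seq, params)
    xi = params.ring_factor
    da = delta[1 : n + 1] * alpha[1 : n + 1]  # delta_i * alpha_i, i=1..N

    log_da_cumsum = np.zeros(n + 1)
    log_da_cumsum[1:] = np.cumsum(np.log(da))

    # prefix: u_{n+1}[0] = u_n[0] + u_n[1]*da_n*delta_{n+1}*xi
    #         u_{n+1}[1] = u_n[0] + u_n[1]*da_n
    log_u1 = np.empty(n + 2)
    u0, u1, scale = 1.0, 1.0, 0.0
    log_u1[1] = scale + math.log(u1)
    for i in range(1, n + 1):
        w = da[i - 1]
        n0 = u0 + u1 * w * delta[i + 1] * xi
        n1 = u0 + u1 * w
        m = max(n0, n1)
        scale += math.log(m)
        u0, u1 = n0 / m, n1 / m
        log_u1[i + 1] = scale + math.log(u1)

    # suffix: v_m[0] = v_{m+1}[0] + v_{m+1}[1]
    #         v_m[1] = da_m * (delta_{m+1}*xi*v_{m+1}[0] + v_{m+1}[1])
    log_v1 = np.empty(n + 2)
    v0, v1, scale = 0.0, 1.0, 0.0
    log_v1[n + 1] = 0.0
    for m in range(n, 0, -1):
        w = da[m - 1]
        n0 = v0 + v1
        n1 = w * (delta[m + 1] * xi * v0 + v1)
        mx = max(n0, n1)
        scale += math.log(mx)
        v0, v1 = n0 / mx, n1 / mx
        log_v1[m] = scale + math.log(v1)

    return log_u1, log_v1, log_da_cumsum


def transfer_partition(seq: NucleotideSequence, params: ThermoParams | None = None) -> ScaledValue:
    """Total partition function Z via the 2x2 transfer-matrix product, O(N).

    Running rescaling keeps intermediates in floating range for sequences of
    10^5 bp and beyond; the result is returned as (mantissa, log_scale).
    """
    params = params or ThermoParams()
    log_u1, _, _ = _prefix_suffix(seq, params)
    log_z = float(log_u1[seq.n + 1])  # Z = u_{N+1}[sigma=1]
    frac, whole = math.modf(log_z)
    return ScaledValue(math.exp(frac), whole)


@dataclass(frozen=True)
class OpeningProfile:
    """Bubble-opening probabilities P_k(n) for one sequence and one bubble size.

    ``values[j]`` is P_k(n) for start position n = j + 1, n in [1, N-k+1]:
    the equilibrium probability that base pairs n .. n+k-1 are open
    simultaneously.
    """

    sequence_id: str
    k: int
    values: np.ndarray
    params_fingerprint: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)

    def at(self, n: int) -> float:
        """P_k(n) at 1-based start position n."""
        if not 1 <= n <= len(self.values):
            raise IndexError(f"start position {n} outside [1, {len(self.values)}]")
        return float(self.values[n - 1])


def opening_profile(
    seq: NucleotideSequence, k: int, params: ThermoParams | None = None
) -> OpeningProfile:
    """P_k(n) = Z_k(n)/Z for every start n in [1, N-k+1], in O(N) total.

    The conditional partition function factorizes across the forced-open
    window: Z_k(n) = u_n[1] * prod_{j=n}^{n+k-2} delta_j alpha_j * v_{n+k-1}[1],
    where u is the left prefix contraction and v the right suffix contraction
    of the transfer-matrix product.  Prefixes, suffixes and the cumulative
    log-sum are each one linear pass; log scale factors cancel in the ratio.
    """
    params = params or ThermoParams()
    n_bp = seq.n
    if not 1 <= k <= n_bp:
        raise ValueError(f"bubble size k={k} outside [1, N={n_bp}]")
    log_u1, log_v1, log_da = _prefix_suffix(seq, params)

    starts = np.arange(1, n_bp - k + 2)
    # sum_{j=n}^{n+k-2} log(delta_j alpha_j) = log_da[n+k-2] - log_da[n-1]
    window = log_da[starts + k - 2] - log_da[starts - 1]
    log_zk = log_u1[starts] + window + log_v1[starts + k - 1]
    log_z = log_u1[n_bp + 1]
    values = np.exp(log_zk - log_z)
    return OpeningProfile(seq.id, k, values, params.fingerprint())
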