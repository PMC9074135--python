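"""Replica-exchange utilities: temperature ladders, exchange statistics,
and the Metropolis neighbour-swap criterion.

The ladder is geometric (exponential spacing), the standard choice for
replica exchange in implicit solvent where heat capacity varies slowly:
T_i = T_min · (T_max/T_min)^(i/(n−1)).  Production ladders generated by
heat-capacity-aware tools will deviate from this; such ladders are accepted
as explicit inputs everywhere a ladder is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "K_B",
    "ExchangeRecord",
    "ExchangeLog",
    "temperature_ladder",
    "exchange_frequency",
    "metropolis_exchange_p",
    "nearest_temperature",
    "read_exchange_log",
    "write_exchange_log",
]

K_B = 0.0019872041      # Boltzmann constant, kcal/(mol·K)


@dataclass(frozen=True)
class ExchangeRecord:
    attempt: int
    replica_i: int
    replica_j: int
    accepted: bool


@dataclass
class ExchangeLog:
    records: list
    n_replicas: int

    def __post_init__(self):
        for r in self.records:
            if abs(r.replica_j - r.replica_i) != 1:
                raise ValueError("exchange attempts must involve ladder neighbours")


def temperature_ladder(t_min: float = 270.0, t_max: float = 615.0,
                       n: int = 10) -> np.ndarray:
    """Geometrically spaced temperatures from t_min to t_max (K)."""
    if n < 2:
        raise ValueError("need at least two replicas")
    if not (t_max > t_min > 0):
        raise ValueError("need t_max > t_min > 0")
    i = np.arange(n)
    return t_min * (t_max / t_min) ** (i / (n - 1))


def exchange_frequency(log: ExchangeLog) -> dict:
    """Overall and per-neighbour-pair acceptance fractions.

    Returns ``{"overall": float, "per_pair": {(i, j): float},
    "attempts_per_pair": {(i, j): int}}``; the attempt-weighted average of
    the per-pair fractions equals the overall fraction.
    """
    if not log.records:
        raise ValueError("empty exchange log")
    att: dict[tuple, int] = {}
    acc: dict[tuple, int] = {}
    for r in log.records:
        pair = (min(r.replica_i, r.replica_j), max(r.replica_i, r.replica_j))
        att[pair] = att.get(pair, 0) + 1
        acc[pair] = acc.get(pair, 0) + int(r.accepted)
    overall = sum(acc.values()) / sum(att.values())
    return {
        "overall": float(overall),
        "per_pair": {p: acc[p] / att[p] for p in sorted(att)},
        "attempts_per_pair": {p: att[p] for p in sorted(att)},
    }


def metropolis_exchange_p(e_i: float, e_j: float, t_i: float, t_j: float) -> float:
    """Acceptance probability for swapping neighbouring replicas.

    p = min(1, exp[(β_i − β_j)(E_i − E_j)]) with β = 1/(k_B T); equal
    energies or equal temperatures always accept.
    """
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be positive")
    beta_i = 1.0 / (K_B * t_i)
    beta_j = 1.0 / (K_B * t_j)
    arg = (beta_i - beta_j) * (e_i - e_j)
    return float(min(1.0, np.exp(min(arg, 0.0))) if arg < 0 else 1.0)


def nearest_temperature(ladder, target: float = 300.0) -> tuple[int, float]:
    """Ladder index and temperature closest to a target; ties take the lower
    temperature."""
    ladder = np.asarray(ladder, dtype=float)
    diffs = np.abs(ladder - target)
    best = np.flatnonzero(diffs == diffs.min())
    idx = int(best[np.argmin(ladder[best])])
    return idx, float(ladder[idx])


# ---------------------------------------------------------------------------
# plain-text log format: one record per line, `attempt i j accepted`

def write_exchange_log(log: ExchangeLog, dest) -> None:
    lines = [f"# n_replicas {log.n_replicas}"]
    for r in log.records:
        lines.append(f"{r.attempt} {r.replica_i} {r.replica_j} {int(r.accepted)}")
    Path(dest).write_text("\n".join(lines) + "\n")


def read_exchange_log(source) -> ExchangeLog:
    n_replicas = 0
    records = []
    for line in Path(source).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts[:1] == ["n_replicas"]:
                n_replicas = int(parts[1])
            continue
        a, i, j, acc = line.split()
        records.append(ExchangeRecord(int(a), int(i), int(j), bool(int(acc))))
    if not n_replicas:
        n_replicas = 1 + max(max(r.replica_i, r.replica_j) for r in records)
    return ExchangeLog(records=records, n_replicas=n_replicas)
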