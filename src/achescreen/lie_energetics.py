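"""Linear interaction energy (LIE) binding free energies from energy traces.

The LIE estimator writes the binding free energy as a linear function of the
differences in mean ligand–surrounding interaction energies between the
bound (complex in water) and unbound (free ligand in water) states:

    dG = alpha * (<V_vdw>_b - <V_vdw>_u) + beta * (<V_cou>_b - <V_cou>_u) + gamma

with empirical coefficients alpha = 0.288, beta = -0.049 and
gamma = -5.88 kcal/mol transferred from a structurally similar shallow-cleft
receptor system.  Traces come in as GROMACS-style XVG time series, one per
state and replica; replicas are aggregated as per-replica estimates whose
mean and standard error of the mean form the reported value.

Internal unit is kcal/mol throughout; kJ/mol inputs are converted at I/O
(1 kcal = 4.184 kJ exactly).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "KJ_PER_KCAL",
    "EnergyTrace",
    "LIEParameters",
    "LieEstimate",
    "read_xvg",
    "write_xvg",
    "trace_mean",
    "lie_estimate",
    "lie_with_uncertainty",
]

#: Exact thermochemical conversion factor.
KJ_PER_KCAL = 4.184

_STATES = ("bound", "unbound")


@dataclass
class EnergyTrace:
    """Ligand–surrounding vdW and Coulomb energies over time for one state.

    ``times`` are in ps and strictly increasing; energies are stored in
    kcal/mol regardless of the file units they were read from
    (``source_units`` records the original).
    """

    times: np.ndarray
    v_vdw: np.ndarray
    v_cou: np.ndarray
    state: str
    replica: int = 1
    source_units: str = "kcal/mol"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.v_vdw = np.asarray(self.v_vdw, dtype=float)
        self.v_cou = np.asarray(self.v_cou, dtype=float)
        if self.state not in _STATES:
            raise ValueError(f"state must be one of {_STATES}, got {self.state!r}")
        if self.replica < 1:
            raise ValueError("replica index must be >= 1")
        n = self.times.size
        if n < 2:
            raise ValueError(f"a trace needs at least 2 frames, got {n}")
        if self.v_vdw.size != n or self.v_cou.size != n:
            raise ValueError("times/v_vdw/v_cou length mismatch")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class LIEParameters:
    """Empirical LIE coefficients (alpha, beta dimensionless; gamma kcal/mol)."""

    alpha: float = 0.288
    beta: float = -0.049
    gamma: float = -5.88

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class LieEstimate:
    """Replica-aggregated LIE estimate: mean, SEM and per-replica values."""

    dg: float
    sem: float
    n_replicas: int
    per_replica: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_replicas < 1 or len(self.per_replica) != self.n_replicas:
            raise ValueError("per_replica length must equal n_replicas >= 1")

    @property
    def single_replica(self) -> bool:
        """True when only one replica was available (SEM is 0 by convention)."""
        return self.n_replicas == 1

    def to_dict(self) -> dict:
        return {
            "dg": self.dg,
            "sem": self.sem,
            "n_replicas": self.n_replicas,
            "per_replica": list(self.per_replica),
            "single_replica": self.single_replica,
        }


_LEGEND_RE = re.compile(r'@\s+s(\d+)\s+legend\s+"([^"]*)"')
_YAXIS_RE = re.compile(r'@\s+yaxis\s+label\s+"([^"]*)"')

_VDW_PAT = re.compile(r"lj|vdw|van\s*der\s*waals|disper", re.IGNORECASE)
_COU_PAT = re.compile(r"coul|electrost", re.IGNORECASE)


def read_xvg(
    path: str | Path,
    state: str = "bound",
    replica: int = 1,
    source_units: str | None = None,
    column_map: Mapping[str, int] | None = None,
) -> EnergyTrace:
    """Parse a GROMACS-dialect XVG energy file into an :class:`EnergyTrace`.

    Lines starting with ``#`` or ``@`` are metadata; the rest are
    whitespace-separated rows of time plus at least two energy columns.  The
    vdW/Coulomb column assignment is taken from the ``@ s0/s1 legend``
    entries when they identify the terms, else from ``column_map`` (0-based
    indices into the energy columns, keys ``vdw``/``cou``).  Units default
    to what the ``@ yaxis label`` declares, falling back to kJ/mol (the
    native GROMACS unit); kJ/mol values are divided by 4.184.
    """
    path = Path(path)
    legends: dict[int, str] = {}
    yaxis = None
    rows: list[list[float]] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@"):
                m = _LEGEND_RE.match(line)
                if m:
                    legends[int(m.group(1))] = m.group(2)
                m = _YAXIS_RE.match(line)
                if m:
                    yaxis = m.group(1)
                continue
            rows.append([float(tok) for tok in line.split()])
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] < 3:
        raise ValueError(f"{path}: need time plus >=2 energy columns")

    vdw_col = cou_col = None
    for idx, label in legends.items():
        if _VDW_PAT.search(label):
            vdw_col = idx
        elif _COU_PAT.search(label):
            cou_col = idx
    if vdw_col is None or cou_col is None:
        if column_map is None:
            raise ValueError(
                f"{path}: cannot identify vdW/Coulomb columns from legends "
                f"{legends or '(none)'}; pass column_map={{'vdw': i, 'cou': j}}"
            )
        vdw_col, cou_col = int(column_map["vdw"]), int(column_map["cou"])

    if source_units is None:
        if yaxis is not None and "kcal" in yaxis.lower():
            source_units = "kcal/mol"
        else:
            source_units = "kJ/mol"
    scale = 1.0 / KJ_PER_KCAL if source_units == "kJ/mol" else 1.0
    return EnergyTrace(
        times=data[:, 0],
        v_vdw=data[:, 1 + vdw_col] * scale,
        v_cou=data[:, 1 + cou_col] * scale,
        state=state,
        replica=replica,
        source_units=source_units,
    )


def write_xvg(trace: EnergyTrace, path: str | Path, units: str = "kcal/mol") -> None:
    """Write a trace in the XVG dialect read back by :func:`read_xvg`."""
    scale = KJ_PER_KCAL if units == "kJ/mol" else 1.0
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# ligand-surrounding interaction energy, state={trace.state}\n")
        fh.write('@    xaxis  label "Time (ps)"\n')
        fh.write(f'@    yaxis  label "({units})"\n')
        fh.write('@ s0 legend "LJ (SR)"\n')
        fh.write('@ s1 legend "Coulomb (SR)"\n')
        for t, v, c in zip(trace.times, trace.v_vdw, trace.v_cou):
            fh.write(f"{t:.6f} {v * scale:.10f} {c * scale:.10f}\n")


def trace_mean(trace: EnergyTrace, equil_fraction: float = 0.2) -> tuple[float, float]:
    """Mean (vdW, Coulomb) energy over the production part of a trace.

    The first ``equil_fraction`` of the simulated time span is discarded as
    equilibration: frames with time >= t_first + equil_fraction * (t_last -
    t_first) are kept.
    """
    if not 0.0 <= equil_fraction < 1.0:
        raise ValueError(f"equil_fraction must be in [0, 1), got {equil_fraction}")
    t0 = trace.times[0] + equil_fraction * (trace.times[-1] - trace.times[0])
    keep = trace.times >= t0
    if not keep.any():
        raise ValueError("no frames survive the equilibration discard")
    return float(trace.v_vdw[keep].mean()), float(trace.v_cou[keep].mean())


def lie_estimate(
    bound: tuple[float, float],
    unbound: tuple[float, float],
    params: LIEParameters = LIEParameters(),
) -> float:
    """LIE free energy from (mean_vdw, mean_cou) pairs of the two states."""
    d_vdw = bound[0] - unbound[0]
    d_cou = bound[1] - unbound[1]
    if not (math.isfinite(d_vdw) and math.isfinite(d_cou)):
        raise ValueError("non-finite mean energies")
    return params.alpha * d_vdw + params.beta * d_cou + params.gamma


def lie_with_uncertainty(
    traces: Iterable[EnergyTrace],
    params: LIEParameters = LIEParameters(),
    equil_fraction: float = 0.2,
    allow_shared_unbound: bool = False,
    pooled: bool = False,
) -> LieEstimate:
    """Replica-aggregated LIE estimate from bound/unbound trace pairs.

    Each replica contributes one dG from its own bound and unbound
    production means; the reported value is their mean with
    SEM = sample-sd / sqrt(n) (sample sd, n-1 denominator; 0 when n = 1,
    flagged via :attr:`LieEstimate.single_replica`).  With
    ``allow_shared_unbound`` a single unbound trace serves every bound
    replica.  ``pooled=True`` concatenates production frames across replicas
    per state before taking means (per-replica values and their SEM are
    still reported alongside for reference).
    """
    tlist = list(traces)
    bound = {t.replica: t for t in tlist if t.state == "bound"}
    unbound = {t.replica: t for t in tlist if t.state == "unbound"}
    if len(bound) != sum(t.state == "bound" for t in tlist):
        raise ValueError("duplicate bound replica indices")
    if len(unbound) != sum(t.state == "unbound" for t in tlist):
        raise ValueError("duplicate unbound replica indices")
    if not bound:
        raise ValueError("no bound-state traces supplied")

    if allow_shared_unbound and len(unbound) == 1:
        shared = next(iter(unbound.values()))
        unbound = {rep: shared for rep in bound}
    if set(bound) != set(unbound):
        raise ValueError(
            f"mismatched replica sets: bound {sorted(bound)} vs "
            f"unbound {sorted(unbound)}"
        )

    reps = sorted(bound)
    b_means = {r: trace_mean(bound[r], equil_fraction) for r in reps}
    u_means = {r: trace_mean(unbound[r], equil_fraction) for r in reps}
    per = tuple(lie_estimate(b_means[r], u_means[r], params) for r in reps)
    n = len(per)

    if pooled:
        def pooled_means(group: dict[int, EnergyTrace]) -> tuple[float, float]:
            kept_v, kept_c = [], []
            for r in reps:
                tr = group[r]
                t0 = tr.times[0] + equil_fraction * (tr.times[-1] - tr.times[0])
                keep = tr.times >= t0
                kept_v.append(tr.v_vdw[keep])
                kept_c.append(tr.v_cou[keep])
            return (
                float(np.concatenate(kept_v).mean()),
                float(np.concatenate(kept_c).mean()),
            )

        dg = lie_estimate(pooled_means(bound), pooled_means(unbound), params)
    else:
        dg = float(np.mean(per))

    sem = float(np.std(per, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    if n == 1:
        warnings.warn("single replica: SEM reported as 0", stacklevel=2)
    return LieEstimate(dg=float(dg), sem=sem, n_replicas=n, per_replica=per)
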