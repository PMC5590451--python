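"""Serialization: trajectory/error-table CSV, metadata sidecars, run config.

CSV numeric columns are written at full double precision (repr round-trip),
so a written trajectory re-read compares bitwise equal to the in-memory one.
Formatted text tables separately round to the benchmark's display precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .experiments import DOUBLING_LADDER, ErrorTable
from .fixtures import SUBJECTS
from .model import DoseMode, DoseRegimen, PKParameters
from .schemes import Grid, Method, Trajectory

__all__ = [
    "RunConfig",
    "parse_config",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_error_table_csv",
    "format_error_table",
    "write_direction_field_csv",
]

_FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    """Validated inputs for one simulation or benchmark run."""

    case: DoseMode
    params: PKParameters
    I0: float = 0.0
    methods: tuple[Method, ...] = (Method.NSFD,)
    h: float | None = None
    N: int | None = None
    T: float = 20.0
    subject: int | None = None

    @property
    def grid(self) -> Grid:
        if self.N is not None:
            return Grid.from_N(self.N, self.T)
        assert self.h is not None
        return Grid.from_h(self.h, self.T)

    @property
    def regimen(self) -> DoseRegimen:
        if self.case == DoseMode.BOLUS:
            return DoseRegimen.bolus()
        return DoseRegimen.infusion(self.I0)


_KNOWN_KEYS = {
    "case", "subject", "k10", "k12", "k21", "I0", "method", "methods",
    "h", "N", "T",
}


def parse_config(source: str | Path | dict[str, Any]) -> RunConfig:
    """Build a RunConfig from a YAML file path or an equivalent mapping.

    Exactly one of ``h`` and ``N`` must be given together with the horizon
    ``T``; the other is derived.  Parameters come either from a ``subject``
    number (1-4) or from explicit ``k10``/``k12``/``k21`` keys.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "case" not in data:
        raise ValueError("missing required key: case")
    case = DoseMode(data["case"])

    subject = data.get("subject")
    if subject is not None:
        if subject not in SUBJECTS:
            raise ValueError(f"subject: must be one of {sorted(SUBJECTS)}")
        params = SUBJECTS[subject].params
    else:
        try:
            params = PKParameters(
                k10=float(data["k10"]), k12=float(data["k12"]), k21=float(data["k21"])
            )
        except KeyError as exc:
            raise ValueError(f"missing rate constant: {exc.args[0]}") from exc
        except ValueError as exc:
            raise ValueError(f"invalid rate constants: {exc}") from exc

    h, N = data.get("h"), data.get("N")
    if (h is None) == (N is None):
        raise ValueError("give exactly one of h, N")
    if h is not None and h <= 0:
        raise ValueError("h: must be positive")
    if N is not None and int(N) < 1:
        raise ValueError("N: must be >= 1")
    T = float(data.get("T", 20.0))
    if T <= 0:
        raise ValueError("T: must be positive")

    methods_raw = data.get("methods", data.get("method", "nsfd"))
    if isinstance(methods_raw, str):
        methods_raw = [methods_raw]
    methods = tuple(Method(m) for m in methods_raw)

    I0 = float(data.get("I0", 1.0 if case == DoseMode.INFUSION else 0.0))
    return RunConfig(
        case=case, params=params, I0=I0, methods=methods,
        h=float(h) if h is not None else None,
        N=int(N) if N is not None else None,
        T=T, subject=subject,
    )


def _metadata(traj: Trajectory, params: PKParameters, regimen: DoseRegimen) -> dict:
    return {
        "method": traj.method.value,
        "params": dataclasses.asdict(params),
        "regimen": {
            "mode": regimen.mode.value, "c0": regimen.c0,
            "p0": regimen.p0, "I0": regimen.I0,
        },
        "grid": {"t0": traj.grid.t0, "h": traj.grid.h, "N": traj.grid.N},
        "units": {"t": "min", "c": "mg/mL", "p": "mg/mL", "I0": "mg/(min*mL)"},
    }


def write_trajectory_csv(
    traj: Trajectory,
    path: str | Path,
    params: PKParameters | None = None,
    regimen: DoseRegimen | None = None,
) -> None:
    """Write `t,c,p` CSV plus a JSON metadata sidecar (<path>.meta.json)."""
    path = Path(path)
    traj.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)
    if params is not None and regimen is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(_metadata(traj, params, regimen), indent=2))


def read_trajectory_csv(path: str | Path, method: Method = Method.ANALYTIC) -> Trajectory:
    """Read a trajectory CSV back into a Trajectory (grid inferred from t)."""
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["t"].to_numpy()
    if len(t) < 2:
        raise ValueError("trajectory needs at least two nodes")
    h = float(t[1] - t[0])
    grid = Grid(h=h, N=len(t) - 1, t0=float(t[0]))
    return Trajectory(grid=grid, c=df["c"].to_numpy(), p=df["p"].to_numpy(), method=method)


def write_error_table_csv(table: ErrorTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def format_error_table(table: ErrorTable) -> str:
    """Plain-text rendering matching the benchmark layout.

    Errors are rounded to 9 decimals for the bolus case and 8 for the
    infusion case, mirroring the reference display precision.
    """
    dec = 9 if table.case == DoseMode.BOLUS else 8
    comp = "c(t)" if table.compartment == "central" else "p(t)"
    lines = [
        f"Absolute Error for {comp}",
        f"{'N':>6} {'h':>10} {'Error in SFD':>15} {'Error in RK45':>15} {'Error in NSFD':>15}",
    ]
    for r in table.rows:
        lines.append(
            f"{r.N:>6} {r.h:>10.5f} {r.err_sfd:>15.{dec}f} "
            f"{r.err_rk45:>15.{dec}f} {r.err_nsfd:>15.{dec}f}"
        )
    return "\n".join(lines)


def write_direction_field_csv(field: pd.DataFrame, path: str | Path) -> None:
    field.to_csv(path, index=False, float_format=_FLOAT_FMT, columns=["c", "p", "dcdt", "dpdt"])
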