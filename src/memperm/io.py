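"""File formats: traces, manifests, profiles, configs, results.

Plain-text formats throughout.  Trace files are two whitespace-delimited
columns (time ps, position nm) and accept both '#' and '@' comment/metadata
lines, so GROMACS pullx .xvg files can be ingested unchanged; writers emit
'#' headers only.  Units are fixed (nm, ps, kJ/mol, K; P in cm/s) and
recorded in headers — no unit auto-detection.  Parsers reject malformed
input rather than coercing it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .diffusivity import DiffusivityProfile, WindowDiffusivity
from .langevin import WindowTrace
from .permeability import PermeabilityResult, ResistivityProfile
from .wham import PmfProfile

__all__ = [
    "RunConfig", "Manifest", "ManifestRow",
    "read_trace", "write_trace",
    "read_manifest", "write_manifest",
    "read_pmf", "write_pmf",
    "read_diffusivity", "write_diffusivity",
    "write_resistivity", "write_result", "read_result",
]

MANIFEST_COLUMNS = ["window_id", "center_nm", "force_constant_kj_mol_nm2",
                    "seed", "trace_path"]


# ---------------------------------------------------------------- run config

@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    temperature_K: float = 310.0
    bin_width_nm: float = 0.02
    smoothing_span_nm: float = 0.05
    bulk_edge_nm: float = 2.0          # |z| >= bulk_edge is bulk water
    z1_nm: float = -2.2
    z2_nm: float = 2.2
    acf_rule: str = "first_zero"
    max_lag_ps: float = 50.0
    membrane_mode: str = "cancer"      # "cancer" | "normal"
    seed: int = 2022
    landscape: str = "membrane_like"
    landscape_params: dict = field(default_factory=dict)
    d0_nm2_per_ps: float = 0.04
    dt_ps: float = 0.01
    n_steps: int = 200_000
    discard_fraction: float = 0.2
    save_stride: int = 10

    def __post_init__(self) -> None:
        for name in ("temperature_K", "bin_width_nm", "smoothing_span_nm",
                     "bulk_edge_nm", "max_lag_ps", "d0_nm2_per_ps", "dt_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.membrane_mode not in ("cancer", "normal"):
            raise ValueError(f"membrane_mode must be 'cancer' or 'normal', "
                             f"got {self.membrane_mode!r}")
        if self.z1_nm >= self.z2_nm:
            raise ValueError("need z1 < z2")
        if self.acf_rule not in ("first_zero", "full"):
            raise ValueError(f"unknown acf_rule {self.acf_rule!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ------------------------------------------------------------------- traces

def read_trace(path, center: float = np.nan, force_constant: float = np.nan,
               seed: int = -1, temperature: float = 310.0) -> WindowTrace:
    """Parse a two-column (time ps, z nm) text trace.

    Lines starting with '#' or '@' are comments/metadata (xvg dialect).
    Malformed lines are reported with their line number; time must be
    strictly monotone increasing.
    """
    path = Path(path)
    times: List[float] = []
    positions: List[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("@"):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, "
                                 f"got {len(parts)}: {s!r}")
            try:
                t, z = float(parts[0]), float(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric data: {s!r}") from None
            if times and t <= times[-1]:
                raise ValueError(f"{path}:{lineno}: non-monotone time "
                                 f"{t} after {times[-1]}")
            times.append(t)
            positions.append(z)
    if not times:
        raise ValueError(f"{path}: no data rows")
    return WindowTrace(center=center, force_constant=force_constant,
                       times=np.array(times), positions=np.array(positions),
                       seed=seed, temperature=temperature)


def write_trace(trace: WindowTrace, path, header_extra: Dict[str, object] | None = None) -> None:
    """Write a trace with full float precision and a '#' metadata header."""
    path = Path(path)
    lines = ["# memperm window trace",
             "# columns: time_ps position_nm",
             f"# center_nm: {trace.center!r}",
             f"# force_constant_kj_mol_nm2: {trace.force_constant!r}",
             f"# temperature_K: {trace.temperature!r}",
             f"# seed: {trace.seed}"]
    for key, val in (header_extra or {}).items():
        lines.append(f"# {key}: {val}")
    body = "\n".join(f"{float(t)!r} {float(z)!r}"
                     for t, z in zip(trace.times, trace.positions))
    path.write_text("\n".join(lines) + "\n" + body + "\n")


# ----------------------------------------------------------------- manifest

@dataclass(frozen=True)
class ManifestRow:
    window_id: str
    center_nm: float
    force_constant: float
    seed: int
    trace_path: Path
    side: str = "outer"


@dataclass(frozen=True)
class Manifest:
    """Window inventory; trace paths resolve relative to the manifest file."""

    rows: Tuple[ManifestRow, ...]
    extra: pd.DataFrame | None = None     # unknown columns, preserved

    def side(self, tag: str) -> List[ManifestRow]:
        return [r for r in self.rows if r.side == tag]

    @property
    def sides(self) -> List[str]:
        return sorted({r.side for r in self.rows})

    def load_traces(self, temperature: float = 310.0) -> List[WindowTrace]:
        return [read_trace(r.trace_path, center=r.center_nm,
                           force_constant=r.force_constant, seed=r.seed,
                           temperature=temperature)
                for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


def read_manifest(path) -> Manifest:
    """Load a TSV manifest; duplicate ids or unresolvable paths are errors."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"window_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest columns {missing}")
    if df["window_id"].duplicated().any():
        dups = df.loc[df["window_id"].duplicated(), "window_id"].tolist()
        raise ValueError(f"{path}: duplicate window_id values {dups}")
    rows = []
    for _, rec in df.iterrows():
        trace_path = (path.parent / str(rec["trace_path"])).resolve()
        if not trace_path.exists():
            raise FileNotFoundError(f"{path}: trace file not found: {rec['trace_path']}")
        side = str(rec["side"]) if "side" in df.columns else \
            ("outer" if float(rec["center_nm"]) <= 0 else "inner")
        rows.append(ManifestRow(window_id=str(rec["window_id"]),
                                center_nm=float(rec["center_nm"]),
                                force_constant=float(rec["force_constant_kj_mol_nm2"]),
                                seed=int(rec["seed"]), trace_path=trace_path,
                                side=side))
    extra_cols = [c for c in df.columns if c not in MANIFEST_COLUMNS + ["side"]]
    extra = df[["window_id"] + extra_cols] if extra_cols else None
    return Manifest(rows=tuple(rows), extra=extra)


def write_manifest(rows: Sequence[ManifestRow], path) -> None:
    path = Path(path)
    recs = []
    for r in rows:
        rel = Path(r.trace_path).resolve()
        try:
            rel = rel.relative_to(path.parent.resolve())
        except ValueError:
            pass
        recs.append({"window_id": r.window_id, "center_nm": r.center_nm,
                     "force_constant_kj_mol_nm2": r.force_constant,
                     "seed": r.seed, "trace_path": str(rel), "side": r.side})
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- profiles

def _header(kind: str, meta: dict) -> str:
    lines = [f"# memperm {kind}"]
    for key in sorted(meta):
        lines.append(f"# {key}: {meta[key]}")
    return "\n".join(lines)


def write_pmf(pmf: PmfProfile, path) -> None:
    """Three-column text: z_nm dG_kJ_mol stderr_kJ_mol (nan where absent)."""
    meta = dict(pmf.meta, reference=pmf.reference, side=pmf.side,
                smoothed=pmf.smoothed)
    err = pmf.stderr if pmf.stderr is not None else np.full(len(pmf), np.nan)
    body = "\n".join(f"{float(z)!r} {float(g)!r} {float(e)!r}"
                     for z, g, e in zip(pmf.z_grid, pmf.dG, err))
    Path(path).write_text(_header("pmf", meta)
                          + "\n# columns: z_nm dG_kJ_mol stderr_kJ_mol\n"
                          + body + "\n")


def read_pmf(path) -> PmfProfile:
    path = Path(path)
    meta: dict = {}
    z, g, e = [], [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if ":" in s:
                key, _, val = s.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            continue
        parts = s.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        try:
            z.append(float(parts[0])); g.append(float(parts[1])); e.append(float(parts[2]))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric data: {s!r}") from None
    if not z:
        raise ValueError(f"{path}: no data rows")
    ga = np.array(g)
    ea = np.array(e)
    return PmfProfile(z_grid=np.array(z), dG=ga,
                      stderr=None if np.all(np.isnan(ea)) else ea,
                      reference=meta.pop("reference", "raw"),
                      side=meta.pop("side", "full"),
                      smoothed=meta.pop("smoothed", "False") == "True",
                      mask=np.isnan(ga), meta=meta)


def write_diffusivity(diff: DiffusivityProfile, path) -> None:
    """z_nm D_nm2_per_ps plus per-window diagnostics in '#' comments."""
    meta = dict(diff.meta, side=diff.side)
    lines = [_header("diffusivity", meta),
             "# per-window: center_nm z_mean_nm var_nm2 acf_integral_nm2_ps "
             "D_nm2_per_ps truncation_lag_ps"]
    for w in diff.windows:
        lines.append(f"# window: {float(w.center)!r} {float(w.z_mean)!r} "
                     f"{float(w.variance)!r} {float(w.acf_integral)!r} "
                     f"{float(w.D)!r} {float(w.truncation_lag)!r}")
    lines.append("# columns: z_nm D_nm2_per_ps")
    lines += [f"{float(z)!r} {float(d)!r}" for z, d in zip(diff.z_grid, diff.D)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_diffusivity(path) -> DiffusivityProfile:
    path = Path(path)
    meta: dict = {}
    windows: List[WindowDiffusivity] = []
    z, d = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("# window:"):
            vals = [float(v) for v in s.split(":", 1)[1].split()]
            windows.append(WindowDiffusivity(center=vals[0], z_mean=vals[1],
                                             variance=vals[2], acf_integral=vals[3],
                                             D=vals[4], truncation_lag=vals[5]))
            continue
        if s.startswith("#"):
            if ":" in s:
                key, _, val = s.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            continue
        parts = s.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        z.append(float(parts[0])); d.append(float(parts[1]))
    if not z:
        raise ValueError(f"{path}: no data rows")
    return DiffusivityProfile(z_grid=np.array(z), D=np.array(d),
                              windows=tuple(windows),
                              side=meta.pop("side", "full"), meta=meta)


def write_resistivity(r: ResistivityProfile, path) -> None:
    meta = dict(r.meta, temperature_K=r.temperature, beta_mol_per_kJ=r.beta)
    body = "\n".join(f"{float(z)!r} {float(v)!r}" for z, v in zip(r.z_grid, r.R))
    Path(path).write_text(_header("resistivity", meta)
                          + "\n# columns: z_nm R_ps_per_nm2\n" + body + "\n")


def write_result(result: PermeabilityResult, path) -> None:
    """Key-value result file (R_eff, P, log P, bounds, temperature)."""
    lines = ["# memperm permeability result"]
    for key, val in result.meta.items():
        lines.append(f"# {key}: {val}")
    lines += [f"R_eff_ps_per_nm\t{result.R_eff!r}",
              f"P_nm_per_ps\t{result.P_nm_per_ps!r}",
              f"P_cm_per_s\t{result.P_cm_per_s!r}",
              f"log10_P\t{result.log10_P!r}",
              f"z1_nm\t{result.z1!r}",
              f"z2_nm\t{result.z2!r}",
              f"temperature_K\t{result.temperature!r}"]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- snapshots

def write_snapshot(snapshot, path) -> None:
    """Plain-text toy bilayer frame: particle records plus lipid blocks.

    ``particle`` lines carry (leaflet, species, x, y, z, mass); each
    ``lipid`` line (leaflet, species, z, mass, triad x1 y1 x2 y2 x3 y3) is
    followed by one ``orient vx vy vz`` line per carbon.
    """
    lines = ["# memperm toy bilayer snapshot",
             f"# box_nm: {snapshot.box[0]!r} {snapshot.box[1]!r} {snapshot.box[2]!r}"]
    for _, r in snapshot.particles.iterrows():
        lines.append(f"particle {r.leaflet} {r.species} {float(r.x)!r} "
                     f"{float(r.y)!r} {float(r.z)!r} {float(r.mass)!r}")
    for lip in snapshot.lipids:
        t = lip.triad_xy.ravel()
        lines.append("lipid " + " ".join(
            [lip.leaflet, lip.species, repr(lip.z), repr(lip.mass)]
            + [repr(float(v)) for v in t]))
        for v in lip.orientations:
            lines.append(f"orient {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot(path):
    from .bilayer import LipidRecord, ToyBilayerSnapshot
    path = Path(path)
    box = None
    rows = []
    lipids = []
    pending = None    # (leaflet, species, z, mass, triad, orientations)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if "box_nm:" in s:
                box = tuple(float(v) for v in s.split("box_nm:")[1].split())
            continue
        parts = s.split()
        tag = parts[0]
        try:
            if tag == "particle":
                rows.append((parts[1], parts[2], float(parts[3]), float(parts[4]),
                             float(parts[5]), float(parts[6])))
            elif tag == "lipid":
                if pending is not None:
                    lipids.append(_finish_lipid(pending, path, lineno))
                triad = np.array([float(v) for v in parts[5:11]]).reshape(3, 2)
                pending = (parts[1], parts[2], float(parts[3]), float(parts[4]),
                           triad, [])
            elif tag == "orient":
                if pending is None:
                    raise ValueError(f"{path}:{lineno}: orient line outside a "
                                     "lipid block")
                pending[5].append([float(v) for v in parts[1:4]])
            else:
                raise ValueError(f"{path}:{lineno}: unknown record {tag!r}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, ValueError) and str(exc).startswith(str(path)):
                raise
            raise ValueError(f"{path}:{lineno}: malformed record: {s!r}") from None
    if pending is not None:
        lipids.append(_finish_lipid(pending, path, lineno))
    if box is None:
        raise ValueError(f"{path}: missing '# box_nm:' header")
    particles = pd.DataFrame(rows, columns=["leaflet", "species", "x", "y", "z",
                                            "mass"])
    return ToyBilayerSnapshot(box=box, lipids=tuple(lipids), particles=particles)


def _finish_lipid(pending, path, lineno):
    from .bilayer import LipidRecord
    leaflet, species, z, mass, triad, orients = pending
    if not orients:
        raise ValueError(f"{path}:{lineno}: lipid block without orientation "
                         "vectors")
    return LipidRecord(leaflet=leaflet, species=species, triad_xy=triad, z=z,
                       orientations=np.array(orients), mass=mass)


def read_result(path) -> Dict[str, float]:
    out: Dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        key, _, val = s.partition("\t")
        out[key] = float(val)
    if not out:
        raise ValueError(f"{path}: empty result file")
    return out
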