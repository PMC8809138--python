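"""Delimited-text serialization of samples, distributions, series and results.

All on-disk formats are plain text.  Energy values are written with 17
significant digits so that write -> read round trips are bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .distributions import EnergyMesh, ReferenceStatistics, SpeciesDistribution
from .er import SolvationResult
from .components import ComponentResult
from .sampling import InsertionSamples, SolutionEnergySamples
from .setschenow import ConcentrationSeries, SetschenowResult

__all__ = [
    "write_solution_samples",
    "write_insertion_samples",
    "load_energy_samples",
    "write_distribution",
    "read_distribution",
    "write_series",
    "read_series",
    "write_solvation_result",
    "write_setschenow_table",
    "sha256_file",
]

_FMT = "%.17g"


def _fmt_list(values: np.ndarray) -> str:
    return ",".join(_FMT % v for v in values)


class SchemaError(ValueError):
    """A data file violates the documented schema (message carries the line number)."""


def sha256_file(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------- samples

def write_solution_samples(samples: SolutionEnergySamples, path: Union[str, Path]) -> None:
    path = Path(path)
    lines = [
        "# ersolv energy samples",
        "# kind: solution",
        f"# temperature: {_FMT % samples.temperature}",
        "# species: " + ",".join(f"{s}:{c}" for s, c in samples.counts().items()),
        "frame\tspecies\tenergies",
    ]
    for f in range(samples.n_frames):
        for sp, arr in samples.energies.items():
            lines.append(f"{f}\t{sp}\t{_fmt_list(arr[f])}")
    path.write_text("\n".join(lines) + "\n")


def write_insertion_samples(samples: InsertionSamples, path: Union[str, Path]) -> None:
    path = Path(path)
    lines = [
        "# ersolv energy samples",
        "# kind: reference",
        f"# temperature: {_FMT % samples.temperature}",
        "# species: " + ",".join(f"{s}:{c}" for s, c in samples.counts().items()),
        f"# n_insertions_per_frame: {samples.n_insertions_per_frame}",
        "insertion\tframe\tspecies\tpx\tpy\tpz\tenergies",
    ]
    for k in range(samples.n_insertions):
        px, py, pz = (_FMT % v for v in samples.positions[k])
        fr = samples.frame_index[k]
        for sp, arr in samples.energies.items():
            lines.append(f"{k}\t{fr}\t{sp}\t{px}\t{py}\t{pz}\t{_fmt_list(arr[k])}")
    path.write_text("\n".join(lines) + "\n")


def _parse_header(raw_lines: list[str]) -> tuple[dict, int]:
    meta: dict = {}
    i = 0
    for i, line in enumerate(raw_lines):
        if not line.startswith("#"):
            break
        if ":" in line:
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    return meta, i


def _parse_energy_list(text: str) -> np.ndarray:
    text = text.strip()
    if not text:
        return np.empty(0)
    return np.fromstring(text, sep=",")


def load_energy_samples(
    path: Union[str, Path], kind: str
) -> Union[SolutionEnergySamples, InsertionSamples]:
    """Read species-tagged pair-energy samples written by this package.

    ``kind`` is "solution" or "reference"; a mismatch with the file header,
    an unknown species tag, or a malformed row raises :class:`SchemaError`
    with the offending line number.
    """
    if kind not in ("solution", "reference"):
        raise ValueError("kind must be 'solution' or 'reference'")
    path = Path(path)
    raw = path.read_text().splitlines()
    meta, start = _parse_header(raw)
    if meta.get("kind") != kind:
        raise SchemaError(
            f"{path}: file kind {meta.get('kind')!r} does not match requested {kind!r}"
        )
    try:
        temperature = float(meta["temperature"])
        counts = {}
        for tok in meta["species"].split(","):
            name, _, c = tok.partition(":")
            counts[name] = int(c)
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed header ({exc})") from exc
    species = list(counts)
    # skip the column-header line
    body = raw[start + 1:]
    offset = start + 2  # 1-based line number of first body line
    rows: dict[tuple[int, str], np.ndarray] = {}
    positions: dict[int, tuple[float, float, float]] = {}
    frame_of: dict[int, int] = {}
    for ln, line in enumerate(body, start=offset):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            if kind == "solution":
                if len(parts) != 3:
                    raise ValueError("expected 3 tab-separated columns")
                fid, sp, elist = int(parts[0]), parts[1], parts[2]
                key = fid
            else:
                if len(parts) != 7:
                    raise ValueError("expected 7 tab-separated columns")
                iid, fid, sp = int(parts[0]), int(parts[1]), parts[2]
                positions[iid] = (float(parts[3]), float(parts[4]), float(parts[5]))
                frame_of[iid] = fid
                elist = parts[6]
                key = iid
            if fid < 0 or (kind == "reference" and key < 0):
                raise ValueError("negative frame/insertion index")
            if sp not in counts:
                raise ValueError(f"unknown species tag {sp!r}")
            e = _parse_energy_list(elist)
            if len(e) != counts[sp]:
                raise ValueError(
                    f"species {sp!r} has {len(e)} energies, expected {counts[sp]}"
                )
        except ValueError as exc:
            raise SchemaError(f"{path}:{ln}: {exc}") from exc
        rows[(key, sp)] = e
    ids = sorted({k for k, _ in rows})
    if ids != list(range(len(ids))):
        raise SchemaError(f"{path}: frame/insertion ids are not contiguous from 0")
    energies = {
        sp: np.array([rows[(i, sp)] for i in ids]).reshape(len(ids), counts[sp])
        for sp in species
    }
    totals = np.zeros(len(ids))
    for arr in energies.values():
        if arr.size:
            totals += arr.sum(axis=1)
    if kind == "solution":
        return SolutionEnergySamples(
            energies=energies, totals=totals, temperature=temperature
        )
    pos = np.array([positions[i] for i in ids]).reshape(len(ids), 3)
    fidx = np.array([frame_of[i] for i in ids], dtype=np.int64)
    return InsertionSamples(
        energies=energies, totals=totals, positions=pos, frame_index=fidx,
        n_insertions_per_frame=int(meta.get("n_insertions_per_frame", 1)),
        temperature=temperature,
    )


# ---------------------------------------------------------- distributions

def write_distribution(
    dist: Union[SpeciesDistribution, ReferenceStatistics],
    path: Union[str, Path],
    second_moment_path: Optional[Union[str, Path]] = None,
) -> None:
    path = Path(path)
    is_ref = isinstance(dist, ReferenceStatistics)
    n_norm = dist.n_insertions if is_ref else dist.n_frames
    dens = dist.density0 if is_ref else dist.density
    over = dist.overflow_mass0 if is_ref else dist.overflow_mass
    emass = dist.energy_mass0 if is_ref else dist.energy_mass
    edges = dist.mesh.edges
    lines = [
        "# ersolv distribution",
        f"# kind: {'reference' if is_ref else 'solution'}",
        f"# species: {dist.species}",
        f"# {'n_insertions' if is_ref else 'n_frames'}: {n_norm}",
        f"# eps_max: {_FMT % dist.mesh.eps_max}",
        "bin_lo\tbin_hi\tdensity\tenergy_mass",
    ]
    for b in range(dist.mesh.n_bins):
        lines.append(
            f"{_FMT % edges[b]}\t{_FMT % edges[b+1]}\t{_FMT % dens[b]}\t{_FMT % emass[b]}"
        )
    # overflow row: density column carries the mass (bin width is infinite)
    lines.append(f"{_FMT % edges[-1]}\tinf\t{_FMT % over}\t{_FMT % emass[-1]}")
    path.write_text("\n".join(lines) + "\n")
    if is_ref and second_moment_path is not None and dist.second_moment is not None:
        np.savetxt(
            second_moment_path, dist.second_moment, fmt=_FMT, delimiter="\t",
            header=f"second moments, {dist.mesh.n_bins + 1} bins (overflow last), "
                   f"species {dist.species}",
        )


def read_distribution(
    path: Union[str, Path],
    second_moment_path: Optional[Union[str, Path]] = None,
) -> Union[SpeciesDistribution, ReferenceStatistics]:
    path = Path(path)
    raw = path.read_text().splitlines()
    meta, start = _parse_header(raw)
    body = [l for l in raw[start + 1:] if l.strip()]
    lo, hi, dens, emass = [], [], [], []
    for line in body:
        a, b, d, e = line.split("\t")
        lo.append(float(a))
        hi.append(float(b))
        dens.append(float(d))
        emass.append(float(e))
    # the edges are every bin_lo; the overflow row's lo is the final finite edge
    mesh = EnergyMesh(edges=np.array(lo))
    if meta.get("kind") == "reference":
        second = None
        if second_moment_path is not None and Path(second_moment_path).exists():
            second = np.loadtxt(second_moment_path, delimiter="\t")
        return ReferenceStatistics(
            mesh=mesh, species=meta["species"],
            density0=np.array(dens[:-1]), overflow_mass0=dens[-1],
            n_insertions=int(meta["n_insertions"]),
            energy_mass0=np.array(emass), second_moment=second,
        )
    return SpeciesDistribution(
        mesh=mesh, species=meta["species"],
        density=np.array(dens[:-1]), overflow_mass=dens[-1],
        n_frames=int(meta["n_frames"]), energy_mass=np.array(emass),
    )


# ----------------------------------------------------------------- series

def write_series(series_list: list[ConcentrationSeries], path: Union[str, Path]) -> None:
    frames = []
    for s in series_list:
        df = s.data.copy()
        df["label"] = s.label
        frames.append(df[["concentration", "replicate_id", "label", "value"]])
    pd.concat(frames).to_csv(path, index=False, float_format="%.17g")


def read_series(path: Union[str, Path]) -> dict[str, ConcentrationSeries]:
    df = pd.read_csv(path)
    req = {"concentration", "replicate_id", "label", "value"}
    if not req.issubset(df.columns):
        raise SchemaError(f"{path}: expected columns {sorted(req)}")
    return {
        str(label): ConcentrationSeries(
            data=g[["concentration", "replicate_id", "value"]].reset_index(drop=True),
            label=str(label),
        )
        for label, g in df.groupby("label")
    }


# ---------------------------------------------------------------- results

def write_solvation_result(
    result: SolvationResult,
    path: Union[str, Path],
    components: Optional[ComponentResult] = None,
    f_profile_dir: Optional[Union[str, Path]] = None,
) -> None:
    """Flat key/value record; optional per-species f(eps) profiles alongside."""
    lines = [
        f"temperature\t{_FMT % result.temperature}",
        f"dG_total\t{_FMT % result.dG_total}",
        f"dG_self\t{_FMT % result.dG_self}",
        f"tail_correction\t{_FMT % result.tail_correction}",
    ]
    for sp, t in result.species_terms.items():
        lines.append(f"dG_{sp}\t{_FMT % t.dG}")
        lines.append(f"mean_interaction_{sp}\t{_FMT % t.mean_interaction}")
        lines.append(f"reorganization_{sp}\t{_FMT % t.reorganization}")
    if components is not None:
        lines.append(f"eps_max\t{_FMT % components.eps_max}")
        for sp in components.species:
            lines.append(f"dG_int_{sp}\t{_FMT % components.dG_int[sp]}")
            lines.append(f"dG_EV_{sp}\t{_FMT % components.dG_EV[sp]}")
    Path(path).write_text("\n".join(lines) + "\n")
    if f_profile_dir is not None:
        d = Path(f_profile_dir)
        d.mkdir(parents=True, exist_ok=True)
        edges = result.mesh.edges
        for sp, t in result.species_terms.items():
            rows = ["bin_lo\tbin_hi\tf"]
            for b in range(result.mesh.n_bins):
                rows.append(f"{_FMT % edges[b]}\t{_FMT % edges[b+1]}\t{_FMT % t.f_profile[b]}")
            rows.append(f"{_FMT % edges[-1]}\tinf\t{_FMT % t.f_profile[-1]}")
            (d / f"f_profile_{sp}.tsv").write_text("\n".join(rows) + "\n")


def read_flat_record(path: Union[str, Path]) -> dict[str, float]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, _, val = line.partition("\t")
        out[key] = float(val)
    return out


def write_setschenow_table(
    results: list[SetschenowResult], path: Union[str, Path]
) -> None:
    rows = [
        {
            "label": r.label,
            "ks": r.ks,
            "ci95_lo": r.ci95[0],
            "ci95_hi": r.ci95[1],
            "slope": r.slope,
            "intercept": r.intercept,
            "r_squared": r.r_squared,
            "r_squared_points": r.r_squared_points,
            "p_value": r.p_value,
            "n_boot": r.n_boot,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_manifest(manifest: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())
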