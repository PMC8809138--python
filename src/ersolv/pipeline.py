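"""End-to-end concentration-scan driver.

One pipeline run mirrors the shape of a salt-effect study: for every ion-pair
count in the scan and every replicate, sample the solution system (solute
present) and the reference system (solute absent, with test insertions),
histogram the species-tagged pair energies, evaluate the ER functional with
its corrections, split each species term into interaction and
excluded-volume parts, and run the Widom oracle on the same insertions;
finally fit Setschenow coefficients (total, per species, per component, and
for the correction terms) over the concentration series with bootstrap
confidence intervals.  Every artefact is a text file; a JSON manifest records
the configuration hash, all seeds, acceptance rates and output checksums, so
any number in the output tables is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .components import energy_domain_split
from .constants import molarity_from_count
from .distributions import build_mesh, histogram_reference, histogram_solution
from .engine import build_configuration, run_sampling
from .er import dispersion_tail_correction, er_free_energy, self_energy_correction
from .oracles import widom
from .sampling import sample_insertions, sample_solution_energies
from .setschenow import ConcentrationSeries, SetschenowResult, fit_with_ci
from .system import SoluteSite, SoluteSpec, SpeciesSpec, SystemSpec

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "default_config",
           "repulsive_salt_config", "binding_cation_config"]

log = logging.getLogger("ersolv.pipeline")


@dataclass
class RunConfig:
    """Everything needed to reproduce one concentration scan."""

    box_length: float
    temperature: float
    r_cut: float
    coulomb_scheme: str
    water: SpeciesSpec
    cation: SpeciesSpec
    anion: SpeciesSpec
    solute: SoluteSpec
    scan: list[int]
    replicates: int
    seed: int
    equilibration_sweeps: int
    production_sweeps: int
    sample_interval: int
    insertions_per_frame: int
    max_disp: float
    eps_min: float
    eps_max: float
    n_linear: int
    n_log: int
    regularize_reference: bool
    n_boot: int
    outdir: str

    def __post_init__(self) -> None:
        if 0 not in self.scan:
            raise ValueError("the concentration scan must include the zero-salt point")
        if len(set(self.scan)) != len(self.scan):
            raise ValueError("scan ion-pair counts must be distinct")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    # ---------------------------------------------------------------- YAML
    def to_dict(self) -> dict:
        d = {
            "system": {
                "box_length": self.box_length,
                "temperature": self.temperature,
                "r_cut": self.r_cut,
                "coulomb_scheme": self.coulomb_scheme,
                "water": _species_dict(self.water),
                "cation": _species_dict(self.cation),
                "anion": _species_dict(self.anion),
                "solute": {
                    "coupling": self.solute.coupling,
                    "sites": [
                        {
                            "offset": list(s.offset),
                            "charge": s.charge,
                            "lj_sigma": s.lj_sigma,
                            "lj_epsilon": s.lj_epsilon,
                            "style": s.style,
                        }
                        for s in self.solute.sites
                    ],
                },
            },
            "sampling": {
                "equilibration_sweeps": self.equilibration_sweeps,
                "production_sweeps": self.production_sweeps,
                "sample_interval": self.sample_interval,
                "insertions_per_frame": self.insertions_per_frame,
                "max_disp": self.max_disp,
                "replicates": self.replicates,
                "seed": self.seed,
            },
            "analysis": {
                "eps_min": self.eps_min,
                "eps_max": self.eps_max,
                "n_linear": self.n_linear,
                "n_log": self.n_log,
                "regularize_reference": self.regularize_reference,
                "n_boot": self.n_boot,
            },
            "scan": list(self.scan),
            "output": self.outdir,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sy = d["system"]
        sa = d["sampling"]
        an = d["analysis"]
        solute = SoluteSpec(
            sites=tuple(
                SoluteSite(
                    offset=tuple(s["offset"]),
                    charge=float(s.get("charge", 0.0)),
                    lj_sigma=float(s["lj_sigma"]),
                    lj_epsilon=float(s["lj_epsilon"]),
                    style=str(s.get("style", "lj")),
                )
                for s in sy["solute"]["sites"]
            ),
            coupling=float(sy["solute"].get("coupling", 1.0)),
        )
        return cls(
            box_length=float(sy["box_length"]),
            temperature=float(sy["temperature"]),
            r_cut=float(sy["r_cut"]),
            coulomb_scheme=sy.get("coulomb_scheme", "none"),
            water=_species_from(sy["water"], "water"),
            cation=_species_from(sy["cation"], "cation"),
            anion=_species_from(sy["anion"], "anion"),
            solute=solute,
            scan=[int(x) for x in d["scan"]],
            replicates=int(sa["replicates"]),
            seed=int(sa["seed"]),
            equilibration_sweeps=int(sa["equilibration_sweeps"]),
            production_sweeps=int(sa["production_sweeps"]),
            sample_interval=int(sa["sample_interval"]),
            insertions_per_frame=int(sa["insertions_per_frame"]),
            max_disp=float(sa.get("max_disp", 0.4)),
            eps_min=float(an["eps_min"]),
            eps_max=float(an.get("eps_max", 20.0)),
            n_linear=int(an.get("n_linear", 150)),
            n_log=int(an.get("n_log", 40)),
            regularize_reference=bool(an.get("regularize_reference", True)),
            n_boot=int(an.get("n_boot", 100_000)),
            outdir=str(d.get("output", "ersolv_run")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def system_spec(self, n_pairs: int, with_solute: bool, seed: int) -> SystemSpec:
        species = (
            self.water,
            SpeciesSpec(name="cation", count=n_pairs, charge=self.cation.charge,
                        lj_sigma=self.cation.lj_sigma,
                        lj_epsilon=self.cation.lj_epsilon, style=self.cation.style),
            SpeciesSpec(name="anion", count=n_pairs, charge=self.anion.charge,
                        lj_sigma=self.anion.lj_sigma,
                        lj_epsilon=self.anion.lj_epsilon, style=self.anion.style),
        )
        return SystemSpec(
            box_length=self.box_length,
            temperature=self.temperature,
            species=species,
            solute=self.solute if with_solute else None,
            r_cut=self.r_cut,
            coulomb_scheme=self.coulomb_scheme,
            seed=seed,
        )


def _species_dict(s: SpeciesSpec) -> dict:
    return {"count": s.count, "charge": s.charge, "lj_sigma": s.lj_sigma,
            "lj_epsilon": s.lj_epsilon, "style": s.style}


def _species_from(d: dict, name: str) -> SpeciesSpec:
    return SpeciesSpec(
        name=name, count=int(d.get("count", 0)), charge=float(d.get("charge", 0.0)),
        lj_sigma=float(d["lj_sigma"]), lj_epsilon=float(d["lj_epsilon"]),
        style=str(d.get("style", "lj")),
    )


def derive_seed(base: int, *key: int) -> int:
    """Stable per-stage seed below 2^31 derived from the run seed."""
    ss = np.random.SeedSequence([int(base)] + [int(k) for k in key])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    fits: dict[str, SetschenowResult]
    series: dict[str, ConcentrationSeries]
    records: dict  # (n_pairs, replicate) -> flat result record


def _tail_inputs(config: RunConfig, spec: SystemSpec):
    """Number densities and mixed solute-site LJ parameters per species."""
    _, _, ssig, seps = config.solute.site_arrays()
    dens, sig, eps = {}, {}, {}
    v = config.box_length**3
    for sp in spec.species:
        dens[sp.name] = sp.count / v
        sig[sp.name] = 0.5 * (sp.lj_sigma + ssig)
        eps[sp.name] = np.sqrt(sp.lj_epsilon * seps)
    return dens, sig, eps


# stage ids used in seed derivation
_S_BUILD_SOL, _S_EQUIL_SOL, _S_PROD_SOL = 0, 1, 2
_S_BUILD_REF, _S_EQUIL_REF, _S_PROD_REF, _S_INSERT = 3, 4, 5, 6
_S_BOOT = 7


def _run_single(config: RunConfig, n_pairs: int, rep: int, rdir: Path,
                resume: bool, prior_hashes: dict) -> dict:
    """Produce (or reuse) the flat result record of one concentration/replicate."""
    rdir.mkdir(parents=True, exist_ok=True)
    result_file = rdir / "result.tsv"
    sol_file = rdir / "solution_samples.tsv"
    ins_file = rdir / "insertion_samples.tsv"

    def _valid(p: Path) -> bool:
        if not p.exists():
            return False
        rel = str(p)
        if rel in prior_hashes and eio.sha256_file(p) != prior_hashes[rel]:
            log.warning("checksum mismatch for %s; regenerating", p)
            return False
        return True

    if resume and _valid(result_file):
        log.info("reusing %s", result_file)
        return eio.read_flat_record(result_file)

    t0 = time.perf_counter()
    if resume and _valid(sol_file):
        sol_samples = eio.load_energy_samples(sol_file, "solution")
    else:
        spec = config.system_spec(n_pairs, True, derive_seed(config.seed, n_pairs, rep, _S_BUILD_SOL))
        traj = build_configuration(spec, spec.seed)
        traj = run_sampling(traj, config.equilibration_sweeps, config.equilibration_sweeps,
                            derive_seed(config.seed, n_pairs, rep, _S_EQUIL_SOL),
                            max_disp=config.max_disp)
        traj = run_sampling(traj, config.production_sweeps, config.sample_interval,
                            derive_seed(config.seed, n_pairs, rep, _S_PROD_SOL),
                            max_disp=config.max_disp)
        sol_samples = sample_solution_energies(traj)
        eio.write_solution_samples(sol_samples, sol_file)
    if resume and _valid(ins_file):
        ins_samples = eio.load_energy_samples(ins_file, "reference")
    else:
        spec0 = config.system_spec(n_pairs, False, derive_seed(config.seed, n_pairs, rep, _S_BUILD_REF))
        traj0 = build_configuration(spec0, spec0.seed)
        traj0 = run_sampling(traj0, config.equilibration_sweeps, config.equilibration_sweeps,
                             derive_seed(config.seed, n_pairs, rep, _S_EQUIL_REF),
                             max_disp=config.max_disp)
        traj0 = run_sampling(traj0, config.production_sweeps, config.sample_interval,
                             derive_seed(config.seed, n_pairs, rep, _S_PROD_REF),
                             max_disp=config.max_disp)
        ins_samples = sample_insertions(
            traj0, config.solute, config.insertions_per_frame,
            derive_seed(config.seed, n_pairs, rep, _S_INSERT))
        eio.write_insertion_samples(ins_samples, ins_file)

    mesh = build_mesh(config.eps_min, config.eps_max, config.n_linear, config.n_log)
    sol_dist = histogram_solution(sol_samples, mesh)
    ref_stats = histogram_reference(ins_samples, mesh)
    spec_corr = config.system_spec(n_pairs, True, 0)
    dens, sig, eps = _tail_inputs(config, spec_corr)
    tail = dispersion_tail_correction(dens, sig, eps, config.r_cut)
    self_e = self_energy_correction(config.solute.net_charge, config.box_length)
    result = er_free_energy(
        sol_dist, ref_stats, config.temperature,
        self_energy=self_e, tail_correction=tail,
        regularize_empty_reference=config.regularize_reference)
    comp = energy_domain_split(result)
    est = widom(ins_samples)
    eio.write_solvation_result(result, result_file, components=comp,
                               f_profile_dir=rdir / "f_profiles")
    with open(result_file, "a") as fh:
        fh.write(f"widom_dG\t{est.dG:.17g}\n")
        fh.write(f"widom_se\t{est.standard_error:.17g}\n")
        for sp, nbad in result.regularized_bins.items():
            fh.write(f"regularized_bins_{sp}\t{nbad}\n")
    log.info("run n_pairs=%d rep=%d done in %.1f s", n_pairs, rep,
             time.perf_counter() - t0)
    return eio.read_flat_record(result_file)


def run_pipeline(config: RunConfig, resume: bool = True) -> PipelineResult:
    """Execute the full concentration scan and Setschenow analysis."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    prior_hashes: dict = {}
    if resume and manifest_path.exists():
        try:
            prior_hashes = eio.read_manifest(manifest_path).get("files", {})
        except (json.JSONDecodeError, OSError):
            prior_hashes = {}
    config.to_yaml(outdir / "config.yaml")

    species_names = ("water", "cation", "anion")
    records: dict = {}
    rows: dict[str, list] = {}
    for n_pairs in config.scan:
        conc = molarity_from_count(n_pairs, config.box_length)
        for rep in range(config.replicates):
            rdir = outdir / f"run_p{n_pairs}_r{rep}"
            rec = _run_single(config, n_pairs, rep, rdir, resume, prior_hashes)
            records[(n_pairs, rep)] = rec
            labels = {
                "total": rec["dG_total"],
                "self": rec["dG_self"],
                "tail": rec["tail_correction"],
            }
            for sp in species_names:
                labels[sp] = rec[f"dG_{sp}"]
                labels[f"int_{sp}"] = rec[f"dG_int_{sp}"]
                labels[f"EV_{sp}"] = rec[f"dG_EV_{sp}"]
            for lab, val in labels.items():
                rows.setdefault(lab, []).append((conc, rep, val))

    series: dict[str, ConcentrationSeries] = {}
    fits: dict[str, SetschenowResult] = {}
    for lab, entries in rows.items():
        conc, reps, vals = zip(*entries)
        series[lab] = ConcentrationSeries.from_arrays(
            conc, vals, replicate_ids=np.array(reps), label=lab)
        if len(config.scan) >= 2:
            fits[lab] = fit_with_ci(
                series[lab], config.temperature, n_boot=config.n_boot,
                seed=derive_seed(config.seed, _S_BOOT, zlib.crc32(lab.encode())))
    eio.write_series(list(series.values()), outdir / "series.csv")
    if fits:
        eio.write_setschenow_table(list(fits.values()), outdir / "setschenow.csv")

    files = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p)] = eio.sha256_file(p)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "scan": {str(n): molarity_from_count(n, config.box_length) for n in config.scan},
        "files": files,
    }
    eio.write_manifest(manifest, manifest_path)
    return PipelineResult(outdir=outdir, manifest=manifest, fits=fits,
                          series=series, records=records)


# ------------------------------------------------------------------ presets

def default_config(outdir: str = "ersolv_run", seed: int = 7, **overrides) -> RunConfig:
    """Dipolar solute in a charged salt solution (shifted-force electrostatics).

    The toy analogue of a polar small molecule in aqueous alkali-halide
    solutions: a neutral two-site dipolar solute, a neutral single-site
    "water", and oppositely charged small cations / large anions, scanned
    over ion-pair counts standing in for 0-1.7 mol/L.
    """
    cfg = dict(
        box_length=18.0,
        temperature=298.15,
        r_cut=8.0,
        coulomb_scheme="shifted-force",
        water=SpeciesSpec("water", 150, 0.0, 3.0, 0.5),
        cation=SpeciesSpec("cation", 0, 0.25, 2.5, 0.3),
        anion=SpeciesSpec("anion", 0, -0.25, 4.2, 0.3),
        solute=SoluteSpec(sites=(
            SoluteSite(offset=(0.0, 0.0, 0.0), charge=0.15, lj_sigma=3.4, lj_epsilon=0.3),
            SoluteSite(offset=(1.4, 0.0, 0.0), charge=-0.15, lj_sigma=3.2, lj_epsilon=0.3),
        )),
        scan=[0, 2, 4, 6],
        replicates=3,
        seed=seed,
        equilibration_sweeps=300,
        production_sweeps=1500,
        sample_interval=10,
        insertions_per_frame=60,
        max_disp=0.45,
        eps_min=-12.0,
        eps_max=20.0,
        n_linear=150,
        n_log=40,
        regularize_reference=True,
        n_boot=100_000,
        outdir=outdir,
    )
    cfg.update(overrides)
    return RunConfig(**cfg)


def repulsive_salt_config(outdir: str = "ersolv_repulsive", seed: int = 11,
                          **overrides) -> RunConfig:
    """Purely repulsive large "ions" (no charges): an excluded-volume salt.

    Both ion species are near-WCA particles (large sigma, negligible well
    depth), so added salt perturbs the solute almost only through cavity
    statistics; the expected signature is a positive Setschenow coefficient
    carried by the excluded-volume component.
    """
    cfg = dict(
        coulomb_scheme="none",
        water=SpeciesSpec("water", 150, 0.0, 3.0, 0.5),
        cation=SpeciesSpec("cation", 0, 0.0, 4.2, 0.3, style="repulsive"),
        anion=SpeciesSpec("anion", 0, 0.0, 4.6, 0.3, style="repulsive"),
        solute=SoluteSpec(sites=(
            SoluteSite(offset=(0.0, 0.0, 0.0), charge=0.0, lj_sigma=3.4, lj_epsilon=0.4),
        )),
        scan=[0, 3, 6, 9],
        seed=seed,
        outdir=outdir,
    )
    cfg.update(overrides)
    return default_config(**cfg)


def binding_cation_config(outdir: str = "ersolv_binding", seed: int = 13,
                          **overrides) -> RunConfig:
    """A strongly solute-attracted "cation-like" species (no charges).

    The cation's deep Lennard-Jones well with the solute emulates binding to
    a polar site; its species contribution to the Setschenow coefficient is
    expected to be negative (salting-in through direct association).  The
    association signal is a small net effect (mean attraction against the
    reorganization penalty), so this scenario runs longer than the others and
    histograms on a coarser mesh to keep the sparse-count noise of the
    log-ratio term below the signal.
    """
    cfg = dict(
        coulomb_scheme="none",
        water=SpeciesSpec("water", 150, 0.0, 3.0, 0.5),
        cation=SpeciesSpec("cation", 0, 0.0, 2.6, 2.2),
        anion=SpeciesSpec("anion", 0, 0.0, 4.0, 0.1),
        solute=SoluteSpec(sites=(
            SoluteSite(offset=(0.0, 0.0, 0.0), charge=0.0, lj_sigma=3.4, lj_epsilon=0.5),
        )),
        scan=[0, 6, 12, 18],
        production_sweeps=4000,
        insertions_per_frame=80,
        n_linear=60,
        n_log=20,
        seed=seed,
        outdir=outdir,
    )
    cfg.update(overrides)
    return default_config(**cfg)
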