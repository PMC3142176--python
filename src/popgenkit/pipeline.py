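"""Config-driven analysis pipeline producing a deterministic result bundle.

A run is described by a YAML or JSON config (see :class:`RunConfig`), names
one or more aligned loci, and switches analyses on per section.  Outputs are
plain TSV/JSON files plus ``manifest.json`` recording package and dependency
versions, the master seed and every derived per-analysis seed, SHA-256 hashes
of all inputs and outputs, and the estimator variants used — enough to rerun
and diff a bundle bit for bit.

Config schema (all analysis sections optional)::

    seed: 1
    loci:
      - name: locusA
        fasta: path/to/aln.fasta
        regions: path/to/regions.tsv     # optional
        labels: path/to/labels.tsv       # optional
        outgroup: seq_id                 # optional
    diversity: {masks: [all, silent]}
    windows: {statistic: pi, window: 100, step: 25, mask: silent}
    neutrality: {reps: 1000, rho_per_site: 0.0}
    recombination: {estimate_rho: true, reps_per_point: 120}
    geneconv: {permutations: 10000, mask: silent}
    haplotypes: {permutations: 1000, fst_variant: hsm}
    mk: {}
    hka: {mask: silent}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from importlib import metadata
from pathlib import Path

import numpy as np
import yaml

from . import diversity, geneconv, haplotypes, ld, neutrality
from .locus import AlignedLocus, classify_sites, read_alignment

logger = logging.getLogger("popgenkit")

# tskit is msprime's engine: not imported directly, but its version matters
# for reproducing simulation output, so the manifest records it too
_DEPENDENCIES = (
    "numpy", "scipy", "biopython", "msprime", "tskit", "scikit-bio",
    "click", "pyyaml",
)


class ConfigError(ValueError):
    pass


class RunConfig:
    """Validated pipeline configuration."""

    def __init__(self, raw: dict, base_dir: Path | None = None):
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        if "loci" not in raw or not raw["loci"]:
            raise ConfigError("config must list at least one locus")
        self.raw = raw
        self.seed = int(raw.get("seed", 0))
        self.base_dir = base_dir or Path(".")
        self.loci = []
        for entry in raw["loci"]:
            if "name" not in entry or "fasta" not in entry:
                raise ConfigError("each locus needs 'name' and 'fasta'")
            self.loci.append(entry)
        names = [e["name"] for e in self.loci]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate locus names")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        raw = (
            json.loads(text)
            if path.suffix == ".json"
            else yaml.safe_load(text)
        )
        return cls(raw, base_dir=path.parent)

    def resolve(self, p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else self.base_dir / q)

    def section(self, name: str) -> dict | None:
        val = self.raw.get(name)
        if val is None:
            return None
        if val is True:
            return {}
        if not isinstance(val, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        return val


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj


def _derived_seeds(master: int, labels: list[str]) -> dict[str, int]:
    """Stable per-analysis seeds (< 2**31) derived from the master seed."""
    out = {}
    for label in labels:
        h = hashlib.sha256(f"{master}:{label}".encode()).digest()
        out[label] = int.from_bytes(h[:4], "big") % (2**31 - 1) + 1
    return out


def _write_tsv(path: Path, header: list[str], rows: list[list]):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    f"{v:.6g}" if isinstance(v, float) else str(v)
                    for v in row
                )
                + "\n"
            )


def _load_locus(cfg: RunConfig, entry: dict) -> AlignedLocus:
    return read_alignment(
        cfg.resolve(entry["fasta"]),
        regions_path=cfg.resolve(entry["regions"]) if entry.get("regions") else None,
        labels_path=cfg.resolve(entry["labels"]) if entry.get("labels") else None,
    )


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all configured analyses; write the bundle; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    locus_names = [e["name"] for e in config.loci]
    seed_labels = [
        f"{name}:{analysis}"
        for name in locus_names
        for analysis in (
            "neutrality", "recombination", "geneconv", "haplotypes",
        )
    ]
    seeds = _derived_seeds(config.seed, seed_labels)

    inputs = {}
    results: dict = {"loci": {}}
    estimators: dict = {}
    div_rows = []

    hka_inputs = []
    for entry in config.loci:
        name = entry["name"]
        for key in ("fasta", "regions", "labels"):
            if entry.get(key):
                inputs[f"{name}:{key}"] = _sha256(config.resolve(entry[key]))
        locus = _load_locus(config, entry)
        lres: dict = {"n": locus.n, "L": locus.L}
        sites = None
        if locus.annotation is not None:
            sites = classify_sites(locus)
            lres["site_classes"] = {
                cls: len(sites.positions(classes=(cls,)))
                for cls in (
                    "synonymous", "nonsynonymous", "intronic", "flanking",
                    "ambiguous",
                )
            }
            lres["indel_events"] = len(locus.indels)

        sec = config.section("diversity")
        if sec is not None:
            masks = sec.get("masks", ["all"])
            lres["diversity"] = {}
            for mask in masks:
                try:
                    rep = diversity.diversity_stats(locus, sites, mask=mask)
                except diversity.UndefinedStatisticError as exc:
                    logger.warning("%s/%s: %s", name, mask, exc)
                    continue
                lres["diversity"][mask] = _jsonable(rep)
                div_rows.append(
                    [name, mask, rep.n, rep.N, rep.S, rep.singletons,
                     rep.pi, rep.theta]
                )
            try:
                lres["gc_fraction"] = diversity.gc_fraction(locus)
            except diversity.UndefinedStatisticError:
                pass
            out_id = entry.get("outgroup")
            if out_id:
                div = diversity.divergence_k(
                    locus, out_id, sites,
                    mask=sec.get("divergence_mask", "all"),
                )
                lres["divergence"] = _jsonable(div)

        sec = config.section("windows")
        if sec is not None:
            series = diversity.sliding_window(
                locus,
                statistic=sec.get("statistic", "pi"),
                window=int(sec.get("window", 100)),
                step=int(sec.get("step", 1)),
                sites=sites,
                mask=sec.get("mask", "silent"),
            )
            _write_tsv(
                outdir / f"{name}.windows.tsv",
                ["start", "end", "midpoint", "value", "valid_sites"],
                [
                    [int(s), int(e), float(m), float(v), int(k)]
                    for s, e, m, v, k in zip(
                        series.starts, series.ends, series.midpoints,
                        series.values, series.valid_sites,
                    )
                ],
            )
            estimators["windows"] = {
                "statistic": series.statistic, "window": series.window,
                "step": series.step, "mask": sec.get("mask", "silent"),
            }

        sec = config.section("neutrality")
        if sec is not None:
            reps = int(sec.get("reps", 0))
            rho = float(sec.get("rho_per_site", 0.0))
            seed = seeds[f"{name}:neutrality"]
            mask = sec.get("mask", "all")
            d = neutrality.tajima_d(
                locus, sites, mask=mask, rho_per_site=rho, reps=reps,
                seed=seed,
            )
            z = neutrality.kelly_zns(
                locus, sites, mask=mask, rho_per_site=rho, reps=reps,
                seed=seed,
            )
            b, q = neutrality.wall_b_q(
                locus, sites, mask=mask, rho_per_site=rho, reps=reps,
                seed=seed,
            )
            lres["neutrality"] = {
                r.statistic: _jsonable(r) for r in (d, z, b, q)
            }
            estimators["neutrality"] = {
                "null": "fixed-S coalescent", "reps": reps,
                "rho_per_site": rho, "mask": mask,
            }

        sec = config.section("recombination")
        if sec is not None:
            mask = sec.get("mask", "all")
            rm = ld.hudson_kaplan_rm(locus, sites, mask=mask)
            lres["recombination"] = {"rm": _jsonable(rm)}
            if sec.get("estimate_rho", True):
                est = ld.estimate_rho(
                    locus, sites, mask=mask,
                    reps_per_point=int(sec.get("reps_per_point", 120)),
                    seed=seeds[f"{name}:recombination"],
                )
                lres["recombination"]["rho"] = _jsonable(est)
                estimators["recombination"] = {"rho_estimator": est.estimator}

        sec = config.section("geneconv")
        if sec is not None:
            scan = geneconv.sawyer_scan(
                locus, sites,
                mask=sec.get("mask", "silent"),
                permutations=int(sec.get("permutations", 10_000)),
                seed=seeds[f"{name}:geneconv"],
            )
            lres["geneconv"] = {
                "n_condensed_sites": scan.n_condensed_sites,
                "sscf": scan.sscf,
                "ssuf": scan.ssuf,
                "sscf_p": _jsonable(scan.sscf_p),
                "n_significant_fragments": len(scan.significant_fragments),
                "mean_significant_physical_length":
                    scan.mean_significant_physical_length,
                "details": _jsonable(scan.details),
            }
            _write_tsv(
                outdir / f"{name}.fragments.tsv",
                ["seq_i", "seq_j", "start", "end", "condensed_length",
                 "physical_length", "outer", "p_value", "significant"],
                [
                    [f.seq_i, f.seq_j, f.start, f.end, f.condensed_length,
                     f.physical_length, int(f.outer),
                     float("nan") if f.p_value is None else float(f.p_value),
                     int(f.significant)]
                    for f in scan.fragments
                ],
            )

        sec = config.section("haplotypes")
        if sec is not None and locus.groups is not None:
            gd = haplotypes.group_differentiation(
                locus,
                permutations=int(sec.get("permutations", 1000)),
                seed=seeds[f"{name}:haplotypes"],
                fst_variant=sec.get("fst_variant", "hsm"),
            )
            gc_res = haplotypes.group_contrast(locus)
            lres["haplotype_groups"] = {
                "differentiation": _jsonable(gd),
                "contrast": _jsonable(gc_res),
            }
            estimators["haplotypes"] = {
                "fst_variant": sec.get("fst_variant", "hsm")
            }

        sec = config.section("mk")
        if sec is not None and entry.get("outgroup") and sites is not None:
            mk = neutrality.mk_test(locus, sites, entry["outgroup"])
            lres["mk"] = _jsonable(mk)

        sec = config.section("hka")
        if sec is not None and entry.get("outgroup"):
            mask = sec.get("mask", "silent")
            rep = diversity.diversity_stats(locus, sites, mask=mask)
            div = diversity.divergence_k(
                locus, entry["outgroup"], sites, mask=mask
            )
            hka_inputs.append(
                {"name": name, "S": rep.S, "K": div.K_raw, "N": rep.N,
                 "n": rep.n}
            )

        results["loci"][name] = lres

    if config.section("hka") is not None and len(hka_inputs) >= 2:
        results["hka"] = _jsonable(neutrality.hka_test(hka_inputs))
        results["hka"]["loci"] = [x["name"] for x in hka_inputs]

    if div_rows:
        _write_tsv(
            outdir / "diversity.tsv",
            ["locus", "mask", "n", "N", "S", "singletons", "pi", "theta"],
            div_rows,
        )

    results_path = outdir / "results.json"
    with open(results_path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)

    versions = {"popgenkit": _package_version()}
    for dep in _DEPENDENCIES:
        try:
            versions[dep] = metadata.version(dep)
        except metadata.PackageNotFoundError:
            versions[dep] = "unavailable"
    outputs = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "seed": config.seed,
        "derived_seeds": seeds,
        "versions": versions,
        "inputs": inputs,
        "outputs": outputs,
        "estimators": estimators,
        "loci": locus_names,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _package_version() -> str:
    try:
        return metadata.version("popgenkit")
    except metadata.PackageNotFoundError:
        return "unknown"
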