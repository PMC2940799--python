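"""YAML-driven simulation scenarios.

A scenario config fully describes one synthetic study: genomes (preset or
explicit chromosome lists), probe counts, tumor groups with planted CNAs,
and optional synteny blocks between the first two genomes. Example::

    genomes:
      mouse: {preset: mouse_like, n_probes: 3080}
      human: {preset: human_like, n_probes: 3500}
    groups:
      - label: brca1
        genome: mouse
        n_samples: 35
        noise_sd: 0.2
        tumor_type_mix: {Epithelial: 0.9, Mesenchymal: 0.1}
        cnas:
          - {chrom: "15", start: 50e6, end: 80e6, direction: gain,
             frequency: 0.6, amplitude_mean: 0.8, amplitude_sd: 0.1}
    synteny_blocks:
      - {chrom_A: "15", start_A: 55e6, chrom_B: "8", start_B: 110e6,
         n_genes: 10, inverted: false}

Seeds for the probe maps and each group derive deterministically from the
scenario seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .genome import GenomeSpec, human_like_genome, mouse_like_genome, uniform_genome
from .io import ACGHGroup, OrthologTable, ProbeMap, write_acgh, write_orthologs
from .simulate import (CNASpec, GroupSpec, SyntenyBlockSpec, build_ortholog_table,
                       build_probe_map, simulate_group, write_events)

_PRESETS = {"mouse_like": mouse_like_genome, "human_like": human_like_genome}


def _parse_genome(name: str, cfg: dict) -> GenomeSpec:
    if "preset" in cfg:
        if cfg["preset"] not in _PRESETS:
            raise ValueError(f"unknown genome preset {cfg['preset']!r}")
        return _PRESETS[cfg["preset"]]()
    if "uniform" in cfg:
        u = cfg["uniform"]
        return uniform_genome(int(u["n_chromosomes"]), int(float(u["chrom_length"])), name)
    chroms = tuple((str(c["name"]), int(float(c["length"]))) for c in cfg["chromosomes"])
    return GenomeSpec(name, chroms)


def _parse_cna(cfg: dict) -> CNASpec:
    whole = bool(cfg.get("whole_chromosome", False))
    return CNASpec(
        chrom=str(cfg["chrom"]),
        start=0 if whole else int(float(cfg["start"])),
        end=1 if whole else int(float(cfg["end"])),
        direction=cfg["direction"],
        frequency=float(cfg["frequency"]),
        amplitude_mean=float(cfg["amplitude_mean"]),
        amplitude_sd=float(cfg.get("amplitude_sd", 0.0)),
        whole_chromosome=whole,
    )


def _parse_group(cfg: dict) -> tuple[str, GroupSpec]:
    mix = cfg.get("tumor_type_mix", {"unknown": 1.0})
    spec = GroupSpec(
        label=str(cfg["label"]),
        n_samples=int(cfg["n_samples"]),
        noise_sd=float(cfg.get("noise_sd", 0.0)),
        cnas=tuple(_parse_cna(c) for c in cfg.get("cnas", [])),
        tumor_type_mix=tuple((str(k), float(v)) for k, v in mix.items()),
    )
    return str(cfg.get("genome", "default")), spec


def run_scenario(config: dict, seed: int) -> dict:
    """Simulate a scenario; returns genomes, probe maps, cohorts, orthologs.

    Returns a dict with keys ``genomes`` (name -> GenomeSpec), ``probe_maps``
    (name -> ProbeMap), ``cohorts`` (group label -> ACGHGroup) and
    ``orthologs`` (OrthologTable or None).
    """
    rng = np.random.default_rng(seed)
    sub_seed = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    genomes: dict[str, GenomeSpec] = {}
    probe_maps: dict[str, ProbeMap] = {}
    for name, gcfg in config["genomes"].items():
        genomes[name] = _parse_genome(name, gcfg)
        probe_maps[name] = build_probe_map(genomes[name],
                                           int(gcfg.get("n_probes", 3080)), sub_seed())

    cohorts: dict[str, ACGHGroup] = {}
    for gcfg in config.get("groups", []):
        genome_name, spec = _parse_group(gcfg)
        if genome_name not in probe_maps:
            raise ValueError(f"group {spec.label!r} references unknown genome {genome_name!r}")
        cohorts[spec.label] = simulate_group(probe_maps[genome_name], spec, sub_seed())

    orthologs: OrthologTable | None = None
    if config.get("synteny_blocks"):
        names = list(genomes)
        if len(names) < 2:
            raise ValueError("synteny blocks need two genomes")
        blocks = [SyntenyBlockSpec(
            chrom_A=str(b["chrom_A"]), start_A=int(float(b["start_A"])),
            chrom_B=str(b["chrom_B"]), start_B=int(float(b["start_B"])),
            n_genes=int(b["n_genes"]), inverted=bool(b.get("inverted", False)),
            gene_length=int(float(b.get("gene_length", 50_000))),
            gene_gap=int(float(b.get("gene_gap", 150_000))),
        ) for b in config["synteny_blocks"]]
        orthologs = build_ortholog_table(genomes[names[0]], genomes[names[1]],
                                         blocks, sub_seed())
    return {"genomes": genomes, "probe_maps": probe_maps,
            "cohorts": cohorts, "orthologs": orthologs}


def run_scenario_file(config_path: str | Path, seed: int, out_dir: str | Path) -> dict:
    """Load a YAML scenario, simulate it, and write all outputs under *out_dir*."""
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    result = run_scenario(config, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, pm in result["probe_maps"].items():
        pm.table.to_csv(out / f"probes_{name}.tsv", sep="\t", index=False)
    for label, cohort in result["cohorts"].items():
        write_acgh(cohort, out / f"acgh_{label}.tsv", out / f"annot_{label}.tsv")
        if cohort.events is not None:
            write_events(cohort.events, out / f"events_{label}.tsv")
    if result["orthologs"] is not None:
        write_orthologs(result["orthologs"], out / "orthologs.tsv")
    return result
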