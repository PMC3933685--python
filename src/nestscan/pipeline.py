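"""Pipeline orchestration: detection → conservation → reports.

A run is driven by a :class:`RunConfig` (typically parsed from YAML):
per-species annotation paths, species role assignments for the
conservation stage, analysis toggles, an output directory and a seed.
Reports are written both as TSV (diffable) and JSON (machine readable),
with a provenance block (package version, config hash, seed) so every
number is reproducible from inputs + config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .annotation_io import read_gff3
from .conservation import (
    PRESENT,
    ABSENT,
    PresenceMatrix,
    REFERENCE_ROLE,
    TEST_ROLE,
    classify_conservation,
    summarize,
)
from .nested_detect import find_nested_pairs, pairs_table

log = logging.getLogger("nestscan")


@dataclass
class Finding:
    severity: str  # error | warning
    message: str


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    species_gff3: dict[str, str] = field(default_factory=dict)
    reference_species: list[str] = field(default_factory=list)
    test_species: list[str] = field(default_factory=list)
    presence_matrix: str | None = None  # TSV path; overrides derivation
    analyses: list[str] = field(default_factory=lambda: ["detect", "conserve"])
    require_different_strand: bool = True
    require_protein_coding: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[Finding]:
    """Static validation; an empty list means the config is runnable."""
    findings: list[Finding] = []
    if "detect" in config.analyses and not config.species_gff3:
        findings.append(Finding("error", "detect enabled but no species annotations"))
    if "conserve" in config.analyses:
        has_matrix = config.presence_matrix is not None
        if not has_matrix and not config.species_gff3:
            findings.append(Finding("error", "conserve enabled but no inputs"))
        if not config.reference_species:
            findings.append(Finding("error", "conserve enabled but no reference species"))
        if not config.test_species:
            findings.append(Finding("error", "conserve enabled but no test species"))
    for sp, path in config.species_gff3.items():
        if not Path(path).exists():
            findings.append(Finding("error", f"annotation for {sp} not found: {path}"))
    if config.presence_matrix and not Path(config.presence_matrix).exists():
        findings.append(
            Finding("error", f"presence matrix not found: {config.presence_matrix}")
        )
    for sp in config.reference_species + config.test_species:
        if config.species_gff3 and not config.presence_matrix and sp not in config.species_gff3:
            findings.append(Finding("error", f"role species {sp!r} has no annotation"))
    return findings


def _derive_presence_matrix(
    annotations: dict[str, Any],
    pairs_by_species: dict[str, list],
    config: RunConfig,
) -> PresenceMatrix:
    """Presence calls by gene symbol across species.

    A pair family is (host symbol, nested symbol) seen in any species;
    a gene is called present in a species iff its symbol occurs there.
    """
    families: dict[tuple[str, str], bool] = {}
    for sp, pairs in pairs_by_species.items():
        ann = annotations[sp]
        for p in pairs:
            host = ann.gene(p.host_id)
            nested = ann.gene(p.nested_id)
            key = (host.symbol, nested.symbol)
            families.setdefault(key, "LRR-superfamily" in nested.family_tags)
    roles = {sp: REFERENCE_ROLE for sp in config.reference_species}
    roles.update({sp: TEST_ROLE for sp in config.test_species})
    matrix = PresenceMatrix(
        pairs=[(h, n, lrr) for (h, n), lrr in sorted(families.items())],
        species_roles=roles,
    )
    symbols = {
        sp: {g.symbol for g in annotations[sp].genes} for sp in roles
        if sp in annotations
    }
    for i, (h, n, _) in enumerate(matrix.pairs):
        for sp in roles:
            present = symbols.get(sp, set())
            matrix.set_call(i, sp, "host", PRESENT if h in present else ABSENT)
            matrix.set_call(i, sp, "nested", PRESENT if n in present else ABSENT)
    return matrix


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and write reports into ``out_dir``.

    Returns the run report as a dict (also written as ``report.json``).
    Missing inputs fail fast before any stage runs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    findings = validate_config(config)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise ValueError(
            "configuration errors: " + "; ".join(f.message for f in errors)
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {
        "provenance": {
            "version": __version__,
            "config_hash": config.digest(),
            "seed": config.seed,
        }
    }

    annotations = {}
    pairs_by_species: dict[str, list] = {}
    if "detect" in config.analyses:
        per_species = {}
        for sp, path in sorted(config.species_gff3.items()):
            log.info("reading annotation for %s", sp)
            ann = read_gff3(path, species=sp)
            annotations[sp] = ann
            pairs = find_nested_pairs(
                ann,
                require_different_strand=config.require_different_strand,
                require_protein_coding=config.require_protein_coding,
            )
            pairs_by_species[sp] = pairs
            df = pairs_table(pairs)
            df.to_csv(out / f"nested_pairs.{sp}.tsv", sep="\t", index=False)
            per_species[sp] = len(pairs)
        report["detect"] = {
            "pairs_per_species": per_species,
            "n_pairs_total": sum(per_species.values()),
        }
        assert report["detect"]["n_pairs_total"] == sum(
            len(v) for v in pairs_by_species.values()
        )

    if "conserve" in config.analyses:
        if config.presence_matrix:
            matrix = PresenceMatrix.from_tsv(config.presence_matrix)
        else:
            matrix = _derive_presence_matrix(annotations, pairs_by_species, config)
        calls = classify_conservation(matrix)
        summary = summarize(calls)
        rows = [
            {
                "pair": c.pair_id,
                "nested_is_LRR": int(c.nested_is_LRR),
                "status": c.status,
                "loss_category": c.loss_category,
                "evidence": c.evidence,
            }
            for c in calls
        ]
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "conservation_calls.tsv", sep="\t", index=False)
        report["conserve"] = summary
        # internal consistency: totals match per-call rows
        assert summary["n_lost"] == sum(1 for r in rows if r["status"] == "lost")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
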