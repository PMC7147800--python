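"""End-to-end orchestration: per-species runs and census-style reports.

``run_all`` drives motif scanning, physicochemical profiling, NLS detection
and classification, codon usage, substitution-pattern estimation and
reconciliation over a flat key=value configuration, and writes one TSV per
stage plus a one-row-per-species summary report shaped like a genomic census
table (total NAC TFs, double-domain and chimeric counts, membrane-bound and
NLS-bearing counts, duplications/losses).

All outputs are deterministic for a fixed config and seed: no timestamps,
stable orderings, and a manifest recording the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

from . import codon_usage, evolution, motif_scan, nls_classify, nls_detect, physchem
from .sequence_io import (
    SequenceIOError,
    pair_protein_cds,
    read_fasta,
    read_newick,
    write_tsv,
)

__all__ = ["ConfigError", "SpeciesReport", "validate_config", "load_config", "run_all"]


class ConfigError(ValueError):
    pass


_DEFAULTS: dict[str, object] = {
    "cutoff": 0.4,
    "decoder": "posterior",
    "min_nls_len": 4,
    "pi_threshold": 7.0,
    "pka_table": "emboss",
    "bipartite_min": 8,
    "bipartite_max": 24,
    "merge_gap": 4,
    "min_core_motifs": 3,
    "domain_window": 200,
    "tm_window": 19,
    "tm_threshold": 1.6,
    "bootstrap": 1000,
    "distance_model": "p",
    "seed": 0,
    "species": "",
    "species_tree": "",
}

_SPECIES_FIELDS = ("proteome", "cds", "alignment", "gene_tree")

_RANGES = {
    "cutoff": (0.0, 1.0, False),  # exclusive bounds
    "pi_threshold": (0.0, 14.0, True),
    "tm_threshold": (-4.5, 4.5, True),
}


def load_config(path: str | Path) -> dict[str, str]:
    """Parse a flat key=value config file ('#' comments allowed)."""
    raw: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
    return raw


def validate_config(raw: dict[str, object] | None = None) -> dict[str, object]:
    """Fill defaults, coerce types, and reject unknown keys / bad ranges."""
    raw = dict(raw or {})
    config: dict[str, object] = dict(_DEFAULTS)
    species_raw = raw.get("species", "")
    if isinstance(species_raw, (list, tuple)):
        species = [str(s) for s in species_raw if s]
        raw["species"] = ",".join(species)
    else:
        species = [s for s in str(species_raw).split(",") if s]
    for key, value in raw.items():
        if key in _DEFAULTS:
            default = _DEFAULTS[key]
            try:
                if isinstance(default, bool):
                    value = str(value).lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    value = int(value)
                elif isinstance(default, float):
                    value = float(value)
                else:
                    value = str(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad value for {key}: {value!r}") from exc
            config[key] = value
            continue
        head, _, tail = key.partition(".")
        if tail in _SPECIES_FIELDS and head in species:
            config[key] = str(value)
            continue
        raise ConfigError(f"unknown config key {key!r}")
    for key, (lo, hi, inclusive) in _RANGES.items():
        v = config[key]
        ok = lo <= v <= hi if inclusive else lo < v < hi
        if not ok:
            raise ConfigError(f"{key}={v} outside allowed range")
    if config["decoder"] not in ("posterior", "viterbi"):
        raise ConfigError(f"unknown decoder {config['decoder']!r}")
    if config["bootstrap"] < 1:
        raise ConfigError("bootstrap must be >= 1")
    config["species"] = species
    return config


@dataclass
class SpeciesReport:
    species_id: str
    total_nac: int
    n_double_domain: int
    n_chimeric: int
    n_tm_bound: int
    n_with_nls: int
    nls_class_histogram: dict[str, int] = field(default_factory=dict)
    duplications: int = 0
    losses: int = 0

    def histogram_str(self) -> str:
        return ",".join(f"{k}:{v}" for k, v in sorted(self.nls_class_histogram.items()))


def _config_hash(config: dict[str, object]) -> str:
    blob = json.dumps(
        {k: config[k] for k in sorted(config)}, sort_keys=True, default=str
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def run_species(
    species_id: str, config: dict[str, object], outdir: Path
) -> SpeciesReport:
    """Run every stage with available inputs for one species."""
    outdir.mkdir(parents=True, exist_ok=True)
    proteome_path = config.get(f"{species_id}.proteome")
    if not proteome_path:
        raise ConfigError(f"species {species_id} has no proteome configured")
    proteins = read_fasta(proteome_path, alphabet="protein")
    catalog = motif_scan.default_catalog()
    params = nls_detect.default_hmm_params()

    summaries = []
    hit_rows = []
    for rec in proteins:
        summary = motif_scan.count_nac_domains(
            rec,
            catalog,
            min_core_motifs=int(config["min_core_motifs"]),
            window=int(config["domain_window"]),
        )
        summaries.append(summary)
        for s, e in summary.domain_intervals:
            hit_rows.append((rec.id, "nac_domain", s, e))
        for hit in summary.nes_hits:
            hit_rows.append((rec.id, hit.pattern_name, hit.start, hit.end))
    write_tsv(
        outdir / "domain_summary.tsv",
        ["id", "nac_domain_count", "is_nac", "is_multi_domain", "chimeric_partners",
         "n_nes_hits"],
        [
            (s.protein_id, s.nac_domain_count, s.is_nac, s.is_multi_domain,
             ";".join(s.chimeric_partners), len(s.nes_hits))
            for s in summaries
        ],
    )
    write_tsv(outdir / "motif_hits.tsv", ["id", "feature", "start", "end"], hit_rows)

    profiles = [
        physchem.profile(
            rec,
            pka_table=str(config["pka_table"]),
            pi_threshold=float(config["pi_threshold"]),
            tm_window=int(config["tm_window"]),
            tm_threshold=float(config["tm_threshold"]),
        )
        for rec in proteins
    ]
    write_tsv(
        outdir / "physchem.tsv",
        ["id", "length", "mw_da", "pi", "charge_class", "n_tm_segments",
         "tm_segments_hydropathy"],
        [
            (
                p.protein_id, p.length,
                "" if p.mw_da != p.mw_da else f"{p.mw_da:.2f}",
                f"{p.pi:.4f}", p.charge_class, len(p.tm_segments),
                ";".join(f"{s}-{e}" for s, e in p.tm_segments),
            )
            for p in profiles
        ],
    )

    calls: list[nls_classify.NlsCall] = []
    for rec in proteins:
        for interval in nls_detect.call_nls(
            rec,
            params,
            cutoff=float(config["cutoff"]),
            decoder=str(config["decoder"]),
            min_len=int(config["min_nls_len"]),
        ):
            calls.append(nls_classify.make_call(rec.id, interval, rec.residues))
    write_tsv(
        outdir / "nls_calls.tsv",
        ["id", "start", "end", "class", "signature", "terminal", "mean_posterior"],
        [
            (c.protein_id, c.interval.start, c.interval.end, c.nls_class,
             c.signature, c.terminal, f"{c.interval.mean_posterior:.4f}")
            for c in calls
        ],
    )
    signatures, census = nls_classify.signature_census(calls)
    write_tsv(
        outdir / "nls_census.tsv",
        ["signature", "count_n_terminal", "count_c_terminal"],
        [(s.signature, s.count_n_terminal, s.count_c_terminal) for s in signatures],
    )
    write_tsv(
        outdir / "nls_census_summary.tsv",
        ["n_unique_n", "n_unique_c", "n_shared", "n_only_n", "n_only_c"],
        [(census.n_unique_n, census.n_unique_c, census.n_shared,
          census.n_only_n, census.n_only_c)],
    )

    cds_path = config.get(f"{species_id}.cds")
    if cds_path:
        cds = read_fasta(cds_path, alphabet="dna")
        pairs = pair_protein_cds(proteins, cds)
        counts = []
        skipped_total = 0
        for pair in pairs:
            try:
                c, skipped = codon_usage.count_codons(pair.cds)
            except ValueError:
                continue  # frame violation: record skipped, not fatal
            counts.append(c)
            skipped_total += skipped
        if counts:
            table = codon_usage.species_summary(species_id, counts, skipped_total)
            frame = table.to_frame()
            frame.to_csv(outdir / "codon_usage.tsv", sep="\t", index=False)

    duplications = losses = 0
    alignment_path = config.get(f"{species_id}.alignment")
    if alignment_path:
        alignment = read_fasta(alignment_path, alphabet="dna")
        pattern = evolution.estimate_pattern(alignment)
        rows = []
        bases = "ACGT"
        for i, b1 in enumerate(bases):
            rows.append(
                (b1, *(f"{pattern.rates[i, j]:.4f}" if i != j else "-"
                       for j in range(4)))
            )
        write_tsv(outdir / "subst_pattern.tsv", ["base", *bases], rows)
        write_tsv(
            outdir / "subst_summary.tsv",
            ["k1_purine", "k2_pyrimidine", "R_bias", "undefined"],
            [(f"{pattern.k1:.4f}", f"{pattern.k2:.4f}", f"{pattern.R:.4f}",
              pattern.undefined)],
        )
    gene_tree_path = config.get(f"{species_id}.gene_tree")
    if gene_tree_path and config.get("species_tree"):
        gene_tree = read_newick(gene_tree_path)
        species_tree = read_newick(str(config["species_tree"]))
        gene_tree.is_rooted = True
        species_tree.is_rooted = True
        if len(gene_tree.seed_node.child_nodes()) > 2:
            gene_tree = evolution.midpoint_root(gene_tree)
        result = evolution.reconcile(gene_tree, species_tree)
        duplications, losses = result.duplications, result.losses
        write_tsv(
            outdir / "reconciliation.tsv",
            ["duplications", "losses", "paralog_gene_count"],
            [(result.duplications, result.losses, result.paralog_gene_count)],
        )

    nac_ids = {s.protein_id for s in summaries if s.is_nac}
    histogram: dict[str, int] = {}
    for call in calls:
        histogram[call.nls_class] = histogram.get(call.nls_class, 0) + 1
    return SpeciesReport(
        species_id=species_id,
        total_nac=len(nac_ids),
        n_double_domain=sum(1 for s in summaries if s.is_multi_domain),
        n_chimeric=sum(
            1 for s in summaries if s.is_nac and s.chimeric_partners
        ),
        n_tm_bound=sum(
            1 for p in profiles if p.is_membrane_bound and p.protein_id in nac_ids
        ),
        n_with_nls=len({c.protein_id for c in calls if c.protein_id in nac_ids}),
        nls_class_histogram=histogram,
        duplications=duplications,
        losses=losses,
    )


def run_all(config: dict[str, object], outdir: str | Path) -> Path:
    """Run the full pipeline; returns the report directory."""
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species = config["species"]
    if not species:
        raise ConfigError("no species configured")
    reports = []
    for sp in species:
        reports.append(run_species(sp, config, outdir / sp))
    write_tsv(
        outdir / "species_report.tsv",
        ["species_id", "total_nac", "n_double_domain", "n_chimeric", "n_tm_bound",
         "n_with_nls", "nls_class_histogram", "duplications", "losses"],
        [
            (r.species_id, r.total_nac, r.n_double_domain, r.n_chimeric,
             r.n_tm_bound, r.n_with_nls, r.histogram_str(), r.duplications,
             r.losses)
            for r in reports
        ],
    )
    try:
        pkg_version = _pkg_version("nactk")
    except Exception:
        pkg_version = "unknown"
    manifest = {
        "package": "nactk",
        "version": pkg_version,
        "config_hash": _config_hash(config),
        "seed": config["seed"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
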