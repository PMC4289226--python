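"""End-to-end orchestration: simulate -> merge -> assemble -> quantify ->
proteome -> selection, with a single config, structured logging, stage
checksums and report generation mirroring the study's table layouts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import assembly, molevol, protevidence, quant, readprep, seqsim

logger = logging.getLogger("venomforge")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

STAGES = ("simulate", "merge", "assemble", "quantify", "proteome", "selection")


@dataclass
class PipelineConfig:
    out_dir: str = "venomforge_run"
    seed: int = 0
    species: tuple[str, str] = ("speciesA", "speciesB")
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    # simulate block: sizes chosen so a full run stays desk-scale
    n_nontoxins: int = 40
    n_read_pairs: int = 20000
    toxin_fraction: float = 0.362
    error_rate: float = 0.001
    divergence_time: float = 0.15
    # merge block
    min_overlap: int = 25
    max_mismatch_fraction: float = 0.05
    # quantify block
    quant_min_identity: float = 0.95
    # proteome block
    detectability: float = 0.6
    # selection block
    rate_method: str = "counting"
    fit_site_models: bool = True
    site_model_max_seqs: int = 8

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in flat.items() if k in known})
        if isinstance(cfg.species, list):
            cfg.species = tuple(cfg.species)
        return cfg

    def simulation_config(self) -> seqsim.SimulationConfig:
        return seqsim.SimulationConfig(
            seed=self.seed,
            n_nontoxins=self.n_nontoxins,
            n_read_pairs=self.n_read_pairs,
            error_rate=self.error_rate,
            divergence_time=self.divergence_time,
            expression=seqsim.ExpressionModel(toxin_fraction=self.toxin_fraction),
            species=self.species,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; return the run manifest.

    Each stage logs one structured line, writes its outputs under the run
    directory, and records parameter values and output checksums in the
    manifest; reruns with the same config reproduce identical checksums.
    A stage failure halts the run with the failing stage named (partial
    outputs are retained on disk).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage, True):
            logger.info("stage=%s status=skipped", stage)
            continue
        t0 = time.time()
        try:
            outputs, counts = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:  # noqa: BLE001 - halt with stage named
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": {str(p.name): _sha256(p) for p in outputs},
            "counts": counts,
            "elapsed_s": round(time.time() - t0, 2),
        }
        logger.info("stage=%s status=ok counts=%s", stage, counts)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, out: Path, state: dict):
    sim = config.simulation_config()
    truth = seqsim.simulate_transcriptomes(sim)
    state["truth"] = truth
    state["sim"] = sim
    files = []
    for sp in sim.species:
        f = out / f"{sp}_transcripts.fasta"
        seqsim.write_transcript_fasta(truth, sp, f)
        files.append(f)
        f = out / f"{sp}_cds.fasta"
        seqsim.write_cds_fasta(truth, sp, f)
        files.append(f)
    pairs = seqsim.simulate_reads(truth, sim, species=sim.species[0])
    state["read_pairs"] = pairs
    r1, r2 = out / "reads_R1.fastq", out / "reads_R2.fastq"
    seqsim.write_paired_fastq(pairs, r1, r2)
    files += [r1, r2]
    rows, present = seqsim.simulate_id_report(
        truth, detectability=config.detectability
    )
    state["id_report"] = rows
    state["present"] = present
    rep = out / "id_report.tsv"
    seqsim.write_id_report(rows, rep)
    files.append(rep)
    truth_file = out / "truth.json"
    truth_file.write_text(truth.to_json())
    files.append(truth_file)
    return files, {
        "transcripts": sum(len(v) for v in truth.transcripts.values()),
        "read_pairs": len(pairs),
        "report_rows": len(rows),
    }


def _stage_merge(config: PipelineConfig, out: Path, state: dict):
    pairs = [
        readprep.ReadPair(p.id, p.read1, p.qual1, p.read2, p.qual2)
        for p in state["read_pairs"]
    ]
    merged, unmerged, stats = readprep.merge_set(
        pairs, config.min_overlap, config.max_mismatch_fraction
    )
    state["merged"] = merged
    f_m = out / "merged.fastq"
    readprep.write_merged_fastq(merged, f_m)
    f_u1, f_u2 = out / "unmerged_R1.fastq", out / "unmerged_R2.fastq"
    readprep.write_unmerged_fastq(unmerged, f_u1, f_u2)
    f_s = out / "merge_stats.json"
    f_s.write_text(stats.to_json())
    return [f_m, f_u1, f_u2, f_s], {
        "merged": stats.n_merged,
        "fraction_merged": round(stats.fraction_merged, 4),
    }


def _stage_assemble(config: PipelineConfig, out: Path, state: dict):
    truth: seqsim.SyntheticTruth = state["truth"]
    sp = config.species[0]
    references = [
        assembly.Transcript(
            id=t.id,
            sequence=t.sequence,
            cds_span=(len(t.utr5), len(t.utr5) + len(t.cds)),
            class_label=t.class_label,
            cluster_id=t.cluster_id,
            abundance=t.expression_weight,
        )
        for t in truth.transcripts[sp]
    ]
    consensus = assembly.reference_consensus(state["merged"], references)
    unique = assembly.deduplicate(consensus)
    refs = [
        assembly.ReferenceProtein(
            id=t.id,
            sequence=t.mature_protein(),
            description=f"{t.class_label} venom toxin",
            class_label=t.class_label,
        )
        for t in truth.transcripts[sp]
        if t.is_toxin
    ]
    annotated, clusters = assembly.annotate_and_name(unique, refs)
    state["assembled"] = annotated
    state["clusters"] = clusters
    f_fa = out / "assembled_transcripts.fasta"
    with open(f_fa, "w") as fh:
        for t in annotated:
            member = (t.id[len(t.cluster_id) :] or "a") if t.cluster_id else "a"
            fh.write(
                f">{t.id}|cluster={t.cluster_id or t.id}|class={t.class_label}"
                f"|member={member}\n{t.sequence}\n"
            )
    f_cl = out / "toxin_clusters.tsv"
    with open(f_cl, "w") as fh:
        fh.write("cluster\tmember\trepresentative\n")
        for cl in clusters:
            for m in cl.members:
                fh.write(f"{cl.name}\t{m}\t{int(m == cl.representative)}\n")
    return [f_fa, f_cl], {
        "assembled": len(annotated),
        "toxin_clusters": len(clusters),
    }


def _stage_quantify(config: PipelineConfig, out: Path, state: dict):
    db = [
        quant.CdsEntry(
            name=t.id,
            sequence=t.cds,
            cluster=t.cluster_id or t.id,
            class_label=t.class_label,
            member=(t.id[len(t.cluster_id) :] or "a") if t.cluster_id else "a",
        )
        for t in state["assembled"]
    ]
    result = quant.map_reads_to_cds(
        state["merged"], db, min_identity=config.quant_min_identity, seed=config.seed
    )
    table = quant.abundance_table(result)
    state["abundance"] = table
    per_class, toxin_total = quant.class_summary(table)
    f_t = out / "abundance_table.tsv"
    quant.write_abundance_tsv(table, f_t)
    f_c = out / "class_summary.json"
    f_c.write_text(
        json.dumps(
            {"per_class": per_class, "toxin_pct_of_total": toxin_total},
            indent=1,
            sort_keys=True,
        )
    )
    return [f_t, f_c], {
        "clusters_quantified": len(table),
        "toxin_pct_of_total": round(toxin_total, 3),
    }


def _stage_proteome(config: PipelineConfig, out: Path, state: dict):
    truth: seqsim.SyntheticTruth = state["truth"]
    sp = config.species[0]
    db = protevidence.build_search_db(
        [(t.id, t.mature_protein()) for t in truth.transcripts[sp]]
    )
    idents, _orphans = protevidence.map_peptides(state["id_report"], db)
    accepted = protevidence.accept_identifications(idents)
    protevidence.group_identifications(accepted)
    toxin_clusters = sorted(
        {
            t.cluster_id
            for t in truth.transcripts[sp]
            if t.is_toxin and t.cluster_id
        }
    )
    xref = protevidence.cross_reference(accepted, toxin_clusters)
    state["accepted"] = accepted
    f_i = out / "protein_identifications.tsv"
    protevidence.write_identifications_tsv(accepted, f_i)
    f_x = out / "proteome_crossref.json"
    f_x.write_text(json.dumps(dataclasses.asdict(xref), indent=1))
    return [f_i, f_x], {
        "accepted": len(accepted),
        "confirmed_clusters": xref.n_confirmed,
        "total_clusters": xref.n_total,
    }


def _stage_selection(config: PipelineConfig, out: Path, state: dict):
    truth: seqsim.SyntheticTruth = state["truth"]
    sp_a, sp_b = config.species
    by_a, by_b = truth.by_id(sp_a), truth.by_id(sp_b)
    prot_a = {t.id: t.mature_protein() for t in truth.transcripts[sp_a]}
    prot_b = {t.id: t.mature_protein() for t in truth.transcripts[sp_b]}
    pairs = molevol.rbh_orthologs(prot_a, prot_b)
    toxin_rates, nontoxin_rates, rows = [], [], []
    for ida, idb in pairs:
        ta, tb = by_a[ida], by_b[idb]
        aligned = molevol.codon_align(
            ta.cds, tb.cds, id_a=ida, id_b=idb, is_toxin=ta.is_toxin
        )
        if aligned is None:
            continue
        rates = molevol.pairwise_rates(aligned, method=config.rate_method)
        rows.append((ida, idb, ta.is_toxin, rates))
        (toxin_rates if ta.is_toxin else nontoxin_rates).append(rates)
    summary = molevol.rate_outlier_analysis(toxin_rates, nontoxin_rates)
    state["rate_summary"] = summary
    f_r = out / "pairwise_rates.tsv"
    with open(f_r, "w") as fh:
        fh.write("pair\tdN\tdS\tomega\ttoxin\texceeds_dN\texceeds_dS\texceeds_omega\n")
        for ida, idb, is_toxin, r in rows:
            fh.write(
                f"{ida}:{idb}\t{_fmt(r.dn)}\t{_fmt(r.ds)}\t{_fmt(r.omega)}\t"
                f"{int(is_toxin)}\t"
                f"{_exceeds(r.dn, summary.thresholds['dN'])}\t"
                f"{_exceeds(r.ds, summary.thresholds['dS'])}\t"
                f"{_exceeds(r.omega, summary.thresholds['omega'])}\n"
            )
    f_s = out / "rate_null_summary.json"
    f_s.write_text(
        json.dumps(
            {
                "thresholds": summary.thresholds,
                "toxin_exceed_counts": summary.toxin_exceed_counts,
                "wilcoxon_p": summary.wilcoxon_p,
            },
            indent=1,
            sort_keys=True,
        )
    )
    outputs = [f_r, f_s]
    counts = {
        "orthologs": len(pairs),
        "toxin_pairs": len(toxin_rates),
    }
    if config.fit_site_models:
        fits = _site_model_analysis(config, truth)
        if fits:
            f_m = out / "site_model_tests.tsv"
            with open(f_m, "w") as fh:
                fh.write(
                    "family\tmodel_null\tneg_lnl_null\tmodel_alt\tneg_lnl_alt\tp\n"
                )
                for fam, null_fit, alt_fit, lrt in fits:
                    fh.write(
                        f"{fam}\t{null_fit.model}\t{null_fit.neg_lnl:.2f}\t"
                        f"{alt_fit.model}\t{alt_fit.neg_lnl:.2f}\t{lrt.p:.3g}\n"
                    )
            outputs.append(f_m)
            counts["site_model_tests"] = len(fits)
            state["site_model_tests"] = fits
    return outputs, counts


def _site_model_analysis(config: PipelineConfig, truth: seqsim.SyntheticTruth):
    """M1a-vs-M2a LRT on the largest toxin family's cross-species alignment."""
    sp_a, sp_b = config.species
    by_class: dict[str, dict[str, str]] = {}
    for sp, tag in ((sp_a, "A"), (sp_b, "B")):
        for t in truth.transcripts[sp]:
            if t.is_toxin:
                by_class.setdefault(t.class_label, {})[f"{t.id}_{tag}"] = t.cds
    fits = []
    if not by_class:
        return fits
    label, seqs = max(by_class.items(), key=lambda kv: len(kv[1]))
    names = sorted(seqs)[: config.site_model_max_seqs]
    lengths = {len(seqs[n]) for n in names}
    if len(names) < 3 or len(lengths) != 1:
        return fits
    aln = {n: seqs[n][3:-3] for n in names}  # drop shared start/stop codons
    tree = molevol.nj_tree(aln)
    null_fit = molevol.fit_site_model(aln, tree, "M1a")
    alt_fit = molevol.fit_site_model(aln, tree, "M2a")
    lrt = molevol.lrt_pvalue(null_fit.neg_lnl, alt_fit.neg_lnl)
    fits.append((label, null_fit, alt_fit, lrt))
    return fits


def _fmt(v) -> str:
    return "NA" if v is None else f"{v:.4f}"


def _exceeds(v, thr) -> int:
    return int(v is not None and v > thr)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "merge": _stage_merge,
    "assemble": _stage_assemble,
    "quantify": _stage_quantify,
    "proteome": _stage_proteome,
    "selection": _stage_selection,
}


# ---------------------------------------------------------------------------
# Report generation
# ---------------------------------------------------------------------------


def make_tables(manifest: dict, out_dir=None) -> list[Path]:
    """Collect stage outputs into report files with documented layouts.

    Percentages follow the expression-table style (3 decimals) and coverage
    the identification-table style (2 decimals); missing stages are skipped
    with a notice.
    """
    run_dir = Path(manifest["config"]["out_dir"])
    report_dir = Path(out_dir) if out_dir else run_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    produced = []
    mapping = {
        "quantify": ["abundance_table.tsv"],
        "proteome": ["protein_identifications.tsv"],
        "selection": ["pairwise_rates.tsv", "site_model_tests.tsv"],
    }
    for stage, names in mapping.items():
        if stage not in manifest["stages"]:
            logger.info("report: stage=%s missing, table skipped", stage)
            continue
        for name in names:
            src = run_dir / name
            if src.exists():
                dst = report_dir / name
                dst.write_text(src.read_text())
                produced.append(dst)
    summary = report_dir / "summary.txt"
    lines = ["venomforge run summary", ""]
    for stage, info in manifest["stages"].items():
        lines.append(f"{stage}: {json.dumps(info['counts'], sort_keys=True)}")
    summary.write_text("\n".join(lines) + "\n")
    produced.append(summary)
    return produced
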