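"""End-to-end orchestration: qc -> score -> compare -> mutate -> profile -> enrich.

Each stage is a pure function of declared inputs plus the configuration;
repeated runs on identical inputs produce byte-identical artifacts.  A run
manifest records the config snapshot, input digests, and seed; failures
remove any partially written outputs.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .aggregation import (
    AggregationProfile,
    SurrogateParams,
    SurrogatePredictor,
    agg_d,
    agg_p,
    project_domains,
)
from .config import PipelineConfig
from .enrichment import enrich, subset_distribution_test
from .io import (
    CodingRecord,
    read_domain_table,
    read_exclusion_list,
    read_fasta,
    read_pair_table,
    read_score_file,
    write_results_table,
)
from .mutagenesis import muttol_delta, summarize_protein
from .profiles import call_hotspots, find_indels, global_align, map_profiles, profile_table_rows
from .qc import build_pair, filter_pairs
from .stats import delta_and_classify, summarize_classification

INPUT_FILES = {
    "cds_a": "cds_a.fasta",
    "cds_b": "cds_b.fasta",
    "pairs": "pairs.tsv",
    "domains": "domains_a.tsv",
    "annotations": "annotations.tsv",
}
OPTIONAL_INPUTS = {"exclusions": "exclusions.txt"}


@dataclass
class PipelineData:
    records_a: dict
    records_b: dict
    pair_rows: list
    domains_a: list
    annotations: pd.DataFrame
    exclusions: set


def load_inputs(data_dir, table: int = 1) -> PipelineData:
    """Resolve and validate every input before any computation starts."""
    data_dir = Path(data_dir)
    paths = {}
    missing = []
    for key, name in INPUT_FILES.items():
        p = data_dir / name
        if not p.exists():
            missing.append(name)
        paths[key] = p
    if missing:
        raise FileNotFoundError(f"missing input files in {data_dir}: {missing}")

    from .io import read_annotation_table

    records_a = {
        r.id: CodingRecord.from_cds(r.id, r.seq, table)
        for r in read_fasta(paths["cds_a"], "dna")
    }
    records_b = {
        r.id: CodingRecord.from_cds(r.id, r.seq, table)
        for r in read_fasta(paths["cds_b"], "dna")
    }
    pair_rows = read_pair_table(paths["pairs"])
    for row in pair_rows:
        if row.protein_id_a not in records_a:
            raise ValueError(f"pair {row.pair_id}: unknown species-A id {row.protein_id_a}")
        if row.protein_id_b not in records_b:
            raise ValueError(f"pair {row.pair_id}: unknown species-B id {row.protein_id_b}")
    domains = read_domain_table(paths["domains"])
    annotations = read_annotation_table(paths["annotations"])
    exc_path = data_dir / OPTIONAL_INPUTS["exclusions"]
    exclusions = read_exclusion_list(exc_path) if exc_path.exists() else set()
    return PipelineData(records_a, records_b, pair_rows, domains, annotations, exclusions)


def make_predictor(config: PipelineConfig):
    if config.predictor.kind == "surrogate":
        params = SurrogateParams(window=config.predictor.window, theta=config.predictor.theta)
        return SurrogatePredictor(params)

    score_dir = Path(config.predictor.score_dir)

    def file_predictor(protein: str, protein_id: str | None = None):
        if protein_id is None:
            raise ValueError("file predictor needs a protein id to locate its score file")
        sf = read_score_file(score_dir / f"{protein_id}.tsv", config.predictor.score_dialect)
        if sf.residues != protein:
            raise ValueError(f"{protein_id}: score-file residues disagree with the sequence")
        return AggregationProfile.from_score_file(sf)

    return file_predictor


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, data_dir, out_dir) -> dict:
    """Execute every stage; returns the machine-readable summary dict."""
    config.validate()
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    data = load_inputs(data_dir, config.mutagenesis.genetic_code)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    started = time.time()

    def emit(name: str, rows, columns=None) -> Path:
        path = out_dir / name
        write_results_table(rows, path, columns=columns)
        written.append(path)
        return path

    try:
        summary: dict = {"stages": {}}
        predictor = make_predictor(config)
        uses_files = config.predictor.kind == "file"

        def profile_of(record: CodingRecord) -> AggregationProfile:
            if uses_files:
                return predictor(record.protein, record.id)
            return predictor.profile(record.id, record.protein)

        # ---- stage 1: qc -------------------------------------------------
        pairs = [
            build_pair(
                row.pair_id,
                data.records_a[row.protein_id_a],
                data.records_b[row.protein_id_b],
                row.is_chaperone_client,
            )
            for row in data.pair_rows
        ]
        result = filter_pairs(
            pairs,
            exclusions=data.exclusions,
            min_similarity=config.qc.min_similarity,
            max_gaps=config.qc.max_gaps,
            max_len=config.qc.max_length,
        )
        emit(
            "qc_report.tsv",
            [
                {
                    "pair_id": p.pair_id,
                    "protein_id_a": p.record_a.id,
                    "protein_id_b": p.record_b.id,
                    "similarity_pct": p.similarity_pct,
                    "gaps_pct": p.gaps_pct,
                    "is_chaperone_client": int(p.is_chaperone_client),
                    "status": p.status,
                }
                for p in sorted(result.all_pairs(), key=lambda p: p.pair_id)
            ],
        )
        summary["stages"]["qc"] = dict(result.counts)
        passed = sorted(result.passed, key=lambda p: p.pair_id)

        # ---- stage 2: score ----------------------------------------------
        profiles_a = {p.pair_id: profile_of(p.record_a) for p in passed}
        profiles_b = {p.pair_id: profile_of(p.record_b) for p in passed}
        agg_rows = []
        for p in passed:
            agg_rows.append(
                {
                    "pair_id": p.pair_id,
                    "agg_p_a": agg_p(profiles_a[p.pair_id]),
                    "agg_p_b": agg_p(profiles_b[p.pair_id]),
                }
            )
        emit("scores_protein.tsv", agg_rows)

        domains_by_protein: dict[str, list] = {}
        for dom in data.domains_a:
            domains_by_protein.setdefault(dom.protein_id, []).append(dom)
        global_alignments = {
            p.pair_id: global_align(p.record_a.protein, p.record_b.protein)
            for p in passed
        }
        domain_rows = []
        n_dropped = 0
        for p in passed:
            doms = domains_by_protein.get(p.record_a.id, [])
            if not doms:
                continue
            aln = global_alignments[p.pair_id]
            projected, dropped = project_domains(
                doms, aln.gapped_a, aln.gapped_b, {p.record_a.id: p.record_b.id}
            )
            n_dropped += len(dropped)
            proj_by_acc = {d.domain_acc: d for d in projected}
            for dom in doms:
                proj = proj_by_acc.get(dom.domain_acc)
                if proj is None:
                    continue
                domain_rows.append(
                    {
                        "pair_id": p.pair_id,
                        "domain_acc": dom.domain_acc,
                        "start_a": dom.start,
                        "end_a": dom.end,
                        "start_b": proj.start,
                        "end_b": proj.end,
                        "agg_d_a": agg_d(profiles_a[p.pair_id], dom),
                        "agg_d_b": agg_d(profiles_b[p.pair_id], proj),
                    }
                )
        emit(
            "scores_domain.tsv",
            domain_rows,
            columns=[
                "pair_id", "domain_acc", "start_a", "end_a",
                "start_b", "end_b", "agg_d_a", "agg_d_b",
            ],
        )
        summary["stages"]["score"] = {
            "n_proteins": len(agg_rows),
            "n_domains": len(domain_rows),
            "n_domains_dropped": n_dropped,
        }

        # ---- stage 3: compare --------------------------------------------
        z_thr = config.classify.z_threshold
        protein_deltas = delta_and_classify(
            [r["pair_id"] for r in agg_rows],
            [r["agg_p_a"] for r in agg_rows],
            [r["agg_p_b"] for r in agg_rows],
            level="protein",
            z_threshold=z_thr,
        )
        emit("deltas_protein.tsv", protein_deltas)
        domain_deltas = []
        if len(domain_rows) >= 3:
            domain_deltas = delta_and_classify(
                [(r["pair_id"], r["domain_acc"]) for r in domain_rows],
                [r["agg_d_a"] for r in domain_rows],
                [r["agg_d_b"] for r in domain_rows],
                level="domain",
                z_threshold=z_thr,
            )
            emit(
                "deltas_domain.tsv",
                [
                    {
                        "pair_id": rec.unit_id[0],
                        "domain_acc": rec.unit_id[1],
                        "value_a": rec.value_a,
                        "value_b": rec.value_b,
                        "delta": rec.delta,
                        "z": rec.z,
                        "cls": rec.cls,
                    }
                    for rec in domain_deltas
                ],
            )
        summary["stages"]["compare"] = summarize_classification(
            protein_deltas, domain_deltas
        )

        # ---- stage 4: mutate ----------------------------------------------
        summaries_a, summaries_b = [], []
        mut_rows = []
        for p in passed:
            sa = summarize_protein(
                p.record_a, predictor if not uses_files else (lambda s, _id=p.record_a.id: predictor(s, _id)),
                denominator=config.mutagenesis.denominator,
                max_len=config.qc.max_length,
            )
            sb = summarize_protein(
                p.record_b, predictor if not uses_files else (lambda s, _id=p.record_b.id: predictor(s, _id)),
                denominator=config.mutagenesis.denominator,
                max_len=config.qc.max_length,
            )
            summaries_a.append(sa)
            summaries_b.append(sb)
            for species, s in (("a", sa), ("b", sb)):
                mut_rows.append(
                    {
                        "pair_id": p.pair_id,
                        "species": species,
                        "protein_id": s.protein_id,
                        "wt_agg_p": s.wt_agg_p,
                        "n_total": s.n_total,
                        "strict_tolerance": s.strict_tolerance,
                        "lenient_tolerance": s.lenient_tolerance,
                        "beneficial_proportion": s.beneficial_proportion,
                        "detrimental_proportion": s.detrimental_proportion,
                    }
                )
        emit("muttol.tsv", mut_rows)
        deltas_mt = muttol_delta(
            [p.pair_id for p in passed], summaries_a, summaries_b, z_threshold=z_thr
        )
        emit("muttol_deltas.tsv", deltas_mt)
        summary["stages"]["mutate"] = {
            "n_pairs": len(passed),
            "n_higher": sum(1 for d in deltas_mt if d.cls == "higher"),
            "n_lower": sum(1 for d in deltas_mt if d.cls == "lower"),
        }
        per_site_a = {p.pair_id: s.per_site for p, s in zip(passed, summaries_a)}
        per_site_b = {p.pair_id: s.per_site for p, s in zip(passed, summaries_b)}

        # ---- stage 5: profile ----------------------------------------------
        significant = [
            rec.unit_id for rec in protein_deltas if rec.cls != "similar"
        ]
        prof_rows, hotspot_rows, indel_rows = [], [], []
        for pair_id in significant:
            aln = global_alignments[pair_id]
            ap = map_profiles(
                aln.gapped_a,
                aln.gapped_b,
                profiles_a[pair_id],
                profiles_b[pair_id],
                per_site_a[pair_id],
                per_site_b[pair_id],
                pair_id=pair_id,
            )
            prof_rows.extend(profile_table_rows(ap))
            for h in call_hotspots(
                ap,
                detrimental_thr=config.profiles.detrimental_threshold,
                beneficial_thr=config.profiles.beneficial_threshold,
            ):
                hotspot_rows.append(
                    {
                        "pair_id": pair_id,
                        "col": h.col_index,
                        "species": h.species,
                        "kind": h.kind,
                        "count": h.count,
                    }
                )
            for species, start, end, length in find_indels(aln.gapped_a, aln.gapped_b):
                indel_rows.append(
                    {
                        "pair_id": pair_id,
                        "species": species,
                        "start_col": start,
                        "end_col": end,
                        "length": length,
                    }
                )
        emit(
            "profiles.tsv", prof_rows,
            columns=[
                "pair_id", "col", "species", "residue", "agg",
                "mut_min", "mut_max", "n_beneficial", "n_detrimental",
            ],
        )
        emit("hotspots.tsv", hotspot_rows,
             columns=["pair_id", "col", "species", "kind", "count"])
        emit("indels.tsv", indel_rows,
             columns=["pair_id", "species", "start_col", "end_col", "length"])
        summary["stages"]["profile"] = {
            "n_pairs_profiled": len(significant),
            "n_hotspots": len(hotspot_rows),
            "n_indels": len(indel_rows),
        }

        # ---- stage 6: enrich -----------------------------------------------
        id_a = {p.pair_id: p.record_a.id for p in passed}
        background = {p.record_a.id for p in passed}
        subsets = {
            "higher": {id_a[r.unit_id] for r in protein_deltas if r.cls == "higher"},
            "lower": {id_a[r.unit_id] for r in protein_deltas if r.cls == "lower"},
        }
        enrich_counts = {}
        for name, subset in subsets.items():
            rows = (
                enrich(
                    subset,
                    background,
                    data.annotations,
                    min_proteins=config.enrichment.min_proteins,
                )
                if subset
                else []
            )
            emit(
                f"enrichment_{name}.tsv", rows,
                columns=[
                    "term_id", "aspect", "k", "n", "K", "N",
                    "fold_enrichment", "log2_fe", "p", "fdr", "direction",
                ],
            )
            enrich_counts[name] = {
                "n_terms_tested": len(rows),
                "n_significant": sum(1 for r in rows if r.fdr < config.enrichment.fdr),
            }

        clients = {p.record_a.id for p in passed if p.is_chaperone_client}
        others = background - clients
        ann = data.annotations[data.annotations["protein_id"].isin(background)]
        terms = sorted(ann["term_id"].unique())
        if clients and others and terms:
            by_term = ann.groupby("term_id")["protein_id"].agg(set)
            counts_c = [len(by_term[t] & clients) for t in terms]
            counts_o = [len(by_term[t] & others) for t in terms]
            chi_rows = subset_distribution_test(counts_c, counts_o, terms)
            emit("client_term_comparison.tsv", chi_rows)
            enrich_counts["client_vs_other_significant"] = sum(
                1 for r in chi_rows if r.fdr < config.enrichment.fdr
            )
        summary["stages"]["enrich"] = enrich_counts

        # ---- summary + manifest --------------------------------------------
        summary_path = out_dir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(summary_path)

        manifest = {
            "tool_version": __version__,
            "config": config.snapshot(),
            "seed": config.seed,
            "inputs": {
                name: _sha256(data_dir / fname)
                for name, fname in INPUT_FILES.items()
            },
            "outputs": {p.name: _sha256(p) for p in written},
            "elapsed_s": round(time.time() - started, 3),
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return summary
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
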