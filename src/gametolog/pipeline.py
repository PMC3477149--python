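"""Per-gametolog analysis pipeline.

``run_gene`` composes the full workflow for one gene: synonymous-divergence
table, NJ tree with codon bootstrap, informative-site topology partition,
conversion tests (runs, fragment permutation, low-divergence windows on a
genomic alignment) and, optionally, divergence dating.  Every stage error is
re-raised with the stage name attached; all numeric outputs are written as
TSV / newick / BED / JSON next to a plain-text log of the decisions applied
(gap exclusions, clamps, redraws).
"""

from __future__ import annotations

import json
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

from . import alignment_io, conversion, dating, divergence, phylogeny


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage
        self.cause = err


@dataclass
class GeneReport:
    gene: str
    divergence_table: list[dict] = field(default_factory=list)
    tree_newick: Optional[str] = None
    site_partition: Optional[dict] = None
    runs: Optional[dict] = None
    fragments: Optional[dict] = None
    low_divergence_regions: list[dict] = field(default_factory=list)
    dating: Optional[dict] = None
    log: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("divergence")
def _divergence_stage(aln, report):
    by_species: dict[str, dict[str, list[int]]] = {}
    for i, tag in enumerate(aln.taxa):
        if tag.chromosome in ("X", "Y"):
            by_species.setdefault(tag.species_code, {}).setdefault(tag.chromosome, []).append(i)
    for species, chroms in sorted(by_species.items()):
        xs, ys = chroms.get("X", []), chroms.get("Y", [])
        if not xs or not ys:
            continue
        pair_results = []
        for i, j in itertools.product(xs, ys):
            pair_results.append(divergence.pairwise_syn(aln.rows[i], aln.rows[j]))
        res = (pair_results[0] if len(pair_results) == 1
               else divergence.mean_pairwise_syn(pair_results))
        if res.n_excluded:
            report.log.append(
                f"divergence {species}: {res.n_excluded} gap/N/stop codons pairwise-deleted")
        report.divergence_table.append({
            "species": species, "n_pairs": len(pair_results),
            "n_codons": res.n_codons, "S": res.S, "Sd": res.Sd,
            "pS": res.pS, "se_pS": res.se_pS, "KS": res.KS, "se_KS": res.se_KS,
        })


@_stage("tree")
def _tree_stage(aln, report, reps, seed, outgroup):
    tree = phylogeny.bootstrap_nj(aln, reps=reps, seed=seed)
    if tree.n_clamped:
        report.log.append(f"tree: {tree.n_clamped} negative NJ branch(es) clamped to 0")
    report.tree_newick = tree.to_newick(root=outgroup if outgroup in aln.ids else None)
    return tree


@_stage("sites")
def _sites_stage(aln, report, roles, position=2):
    order = [roles["EX"], roles["EY"], roles["MX"], roles["MY"]]
    sites = alignment_io.codon_position_sites(aln, order, position=position)
    counts = phylogeny.classify_informative_sites(sites)
    report.site_partition = {
        "nA": counts.nA, "nB": counts.nB, "nC": counts.nC,
        "n_skipped": counts.n_skipped, "positions": counts.positions,
    }
    return counts


@_stage("runs")
def _runs_stage(counts, report, classes=("A", "B")):
    labeled = sorted(
        [(pos, c) for c in classes for pos in counts.positions[c]])
    labels = [c for _, c in labeled]
    if len(set(labels)) < 2:
        report.log.append("runs: fewer than two site classes present; test skipped")
        return
    res = conversion.runs_test(labels)
    report.runs = {"n1": res.n1, "n2": res.n2, "runs": res.runs_observed,
                   "p_one_tailed": res.p_one_tailed, "method": res.method}


@_stage("fragments")
def _fragments_stage(aln, report, n_perm, seed):
    res = conversion.fragment_permutation_test(aln, n_perm=n_perm, seed=seed)
    report.fragments = {
        "p_global": res.p_global, "observed_statistic": res.observed_statistic,
        "n_polymorphic": res.n_polymorphic, "n_perm": res.n_perm,
        "best_fragments": [f.__dict__ for f in res.fragments[:5]],
    }


@_stage("windows")
def _windows_stage(genomic_aln, pair, report, window_size, alpha):
    seq1, seq2 = genomic_aln.row(pair[0]), genomic_aln.row(pair[1])
    profile = divergence.window_profile(seq1, seq2, window_size=window_size)
    regions = conversion.detect_low_divergence(profile, alpha=alpha)
    report.low_divergence_regions = [r.__dict__ for r in regions]
    return profile, regions


@_stage("dating")
def _dating_stage(report, cfg):
    m_hi, m_lo = dating.autosomal_rate(cfg["K_calibration"],
                                       cfg["T_lo_years"], cfg["T_hi_years"],
                                       rounding=cfg.get("rounding", "printed-chain"))
    model = dating.build_rate_model(m_lo, m_hi, alpha=cfg.get("alpha", 2.0),
                                    rounding=cfg.get("rounding", "printed-chain"))
    est = dating.date_divergence(cfg["KS"], model)
    report.dating = {
        "KS": cfg["KS"], "alpha": model.alpha,
        "m_A": [model.m_A_lo, model.m_A_hi],
        "m_X": [model.m_X_lo, model.m_X_hi],
        "m_Y": [model.m_Y_lo, model.m_Y_hi],
        "m_XY": [model.m_XY_lo, model.m_XY_hi],
        "T_mya": [est.T_lo, est.T_hi],
    }


def run_gene(config: dict[str, Any], outdir: Optional[str] = None) -> GeneReport:
    """Run the composite analysis for one gene from a config mapping.

    Recognised keys: ``gene``, ``alignment`` (FASTA), ``tags`` (TSV),
    ``genomic_alignment``/``genomic_pair``, ``roles`` (EX/EY/MX/MY record
    ids), ``outgroup``, ``bootstrap_reps``, ``n_perm``, ``window_size``,
    ``region_alpha``, ``site_position`` (codon position for the informative
    site partition, default 2), ``seed``, ``dating`` (K_calibration,
    T_lo_years, T_hi_years, KS, alpha).
    """
    report = GeneReport(gene=config.get("gene", "gene"))
    seed = int(config.get("seed", 0))

    try:
        tag_map = (alignment_io.read_tag_map(config["tags"])
                   if config.get("tags") else {})
        aln = alignment_io.read_alignment(config["alignment"], mode="codon",
                                          tag_map=tag_map)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", exc) from exc

    _divergence_stage(aln, report)
    _tree_stage(aln, report, reps=int(config.get("bootstrap_reps", 1000)),
                seed=seed, outgroup=config.get("outgroup"))

    roles = config.get("roles")
    if roles:
        counts = _sites_stage(aln, report, roles,
                              position=int(config.get("site_position", 2)))
        _runs_stage(counts, report)
    _fragments_stage(aln, report, n_perm=int(config.get("n_perm", 10_000)),
                     seed=seed)

    if config.get("genomic_alignment"):
        g_aln = alignment_io.read_alignment(config["genomic_alignment"],
                                            mode="genomic", tag_map=tag_map)
        pair = config.get("genomic_pair", g_aln.ids[:2])
        _windows_stage(g_aln, pair, report,
                       window_size=int(config.get("window_size", 500)),
                       alpha=float(config.get("region_alpha", 0.001)))

    if config.get("dating"):
        _dating_stage(report, config["dating"])

    if outdir:
        _write_outputs(report, Path(outdir))
    return report


def _write_outputs(report: GeneReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"{report.gene}.report.json").write_text(report.to_json())
    if report.divergence_table:
        header = list(report.divergence_table[0])
        lines = ["\t".join(header)]
        for row in report.divergence_table:
            lines.append("\t".join(
                f"{row[k]:.4f}" if isinstance(row[k], float) else str(row[k])
                for k in header))
        (outdir / f"{report.gene}.divergence.tsv").write_text("\n".join(lines) + "\n")
    if report.tree_newick:
        (outdir / f"{report.gene}.nwk").write_text(report.tree_newick + "\n")
    if report.low_divergence_regions:
        bed = "\n".join(
            f"aln\t{r['start']}\t{r['end']}\tlow_divergence\t{r['z']:.3f}"
            for r in report.low_divergence_regions)
        (outdir / f"{report.gene}.regions.bed").write_text(bed + "\n")
    (outdir / f"{report.gene}.log").write_text("\n".join(report.log) + "\n")
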