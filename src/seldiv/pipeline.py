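"""End-to-end analysis pipeline: config in, structured report out.

Stages run in dependency order: sequence preparation (back-translation and
gap-column filtering), tree construction (NJ with bootstrap unless a tree is
supplied), then any enabled combination of 4DTv paralog dating, codon
site/branch model tests, Type-I/Type-II functional divergence, and the SDP
scan. Results land in one JSON report plus per-stage TSVs; runs are
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codon_models import (
    FitSettings,
    fit_branch_model,
    fit_site_model,
    likelihood_ratio_test,
    positively_selected_sites,
)
from .fourdtv import d4dtv_table
from .func_divergence import (
    PARTITIONS,
    change_count_table,
    fit_type1,
    fit_type2,
    type1_caas,
)
from .phylo import bootstrap_support, read_newick, write_newick
from .sdp import sdp_scan
from .seqio import (
    GroupAssignment,
    backtranslate,
    filter_codon_columns,
    read_fasta,
    ProteinAlignment,
)

logger = logging.getLogger(__name__)

_STOCHASTIC_STAGES = ("run_tree", "run_sdp")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; unknown keys in the YAML are errors."""

    protein_alignment: str = ""
    cds: str = ""
    tree: str | None = None
    groups: str | None = None
    out_dir: str = "seldiv_out"
    seed: int | None = None
    min_present: int = 3

    run_tree: bool = True
    tree_mode: str = "nucleotide"
    tree_deletion: str = "pairwise"
    bootstrap_reps: int = 1000

    run_fourdtv: bool = True
    fourdtv_pairs: str = "all"  # "all" or a TSV of id pairs

    run_site_models: bool = True
    site_models: str = "M0,M3,M7,M8"
    pss_high: float = 0.95
    pss_floor: float = 0.7

    run_branch_models: bool = False

    run_diverge: bool = True
    q_threshold: float = 0.9
    type2_band_low: float = 0.8
    type2_band_high: float = 0.9
    property_partition: str = "charge"

    run_sdp: bool = True
    sdp_shuffles: int = 1000
    sdp_pseudocount: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.protein_alignment:
            raise ValueError("config requires protein_alignment")
        for key in ("protein_alignment", "cds", "tree", "groups"):
            val = getattr(self, key)
            if val and not Path(val).exists():
                raise ValueError(f"{key} file not found: {val}")
        if not self.cds and (self.run_fourdtv or self.run_site_models or self.run_branch_models):
            raise ValueError("codon-based stages require a cds file")
        if (self.run_diverge or self.run_sdp) and not self.groups:
            raise ValueError("diverge/sdp stages require a groups file")
        stochastic = (self.run_tree and self.tree is None) or self.run_sdp
        if stochastic and self.seed is None:
            raise ValueError("seed is required when bootstrap or SDP shuffling is enabled")
        if self.property_partition not in PARTITIONS:
            raise ValueError(
                f"unknown property_partition {self.property_partition!r}; "
                f"choose from {sorted(PARTITIONS)}"
            )


def _annotated_newick(tree: dendropy.Tree, omega: dict[str, float], flagged: set[str]) -> str:
    """Newick with per-branch omega and '#flagged' marks as node decorations."""

    def render(node, key_hint: str) -> str:
        if node.is_leaf():
            base = node.taxon.label
            key = base
        else:
            inner = ",".join(
                render(c, f"node{i}") for i, c in enumerate(node.child_nodes())
            )
            base = f"({inner})"
            key = node.label or key_hint
        deco = ""
        if key in omega:
            deco = f"[w={omega[key]:.4f}{'#flagged' if key in flagged else ''}]"
        length = f":{node.edge.length:.6f}" if node.edge.length is not None else ""
        return f"{base}{deco}{length}"

    return render(tree.seed_node, "root") + ";"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages; returns the report dict (also written to JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "metadata": {
            "seldiv_version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "generated_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    }

    # --- sequence stage ---
    t0 = time.time()
    protein = ProteinAlignment(read_fasta(config.protein_alignment, "protein"))
    codon = None
    if config.cds:
        cds = read_fasta(config.cds, "nucleotide")
        codon, removed = filter_codon_columns(
            backtranslate(protein, cds), config.min_present
        )
        report["seqio"] = {
            "n_seqs": codon.n_seqs,
            "n_codon_cols": codon.n_codon_cols,
            "removed_columns": removed,
        }
    logger.info("seqio stage done in %.2fs", time.time() - t0)

    # --- tree stage ---
    tree = None
    if config.tree:
        tree = read_newick(config.tree)
    elif config.run_tree:
        t0 = time.time()
        aln_for_tree = codon if (codon and config.tree_mode != "protein") else protein
        tree = bootstrap_support(
            aln_for_tree,
            mode=config.tree_mode,
            deletion=config.tree_deletion,
            n_reps=config.bootstrap_reps,
            seed=config.seed,
        )
        write_newick(tree, out / "njtree.nwk")
        report["tree"] = {"file": "njtree.nwk", "bootstrap_reps": config.bootstrap_reps}
        logger.info("tree stage done in %.2fs", time.time() - t0)

    groups = GroupAssignment.from_tsv(config.groups) if config.groups else None

    # --- 4DTv ---
    if config.run_fourdtv and codon is not None:
        if config.fourdtv_pairs == "all":
            pairs = list(combinations(codon.ids, 2))
        else:
            pairs = [
                tuple(line.split("\t"))
                for line in Path(config.fourdtv_pairs).read_text().splitlines()
                if line.strip() and not line.startswith("#")
            ]
        table = d4dtv_table(codon, pairs)
        table.to_csv(out / "fourdtv.tsv", sep="\t", index=False)
        report["fourdtv"] = table.to_dict(orient="records")

    # --- codon site models ---
    if config.run_site_models and codon is not None and tree is not None:
        t0 = time.time()
        settings = FitSettings(seed=config.seed or 0)
        names = [m.strip() for m in config.site_models.split(",") if m.strip()]
        fits = {}
        for name in names:
            init = fits.get("M0") if name != "M0" else None
            if name == "M8" and "M7" in fits:
                init = fits["M7"]
            fits[name] = fit_site_model(codon, tree, name, settings, init_fit=init)
        rows, lrts = [], {}
        for name, fit in fits.items():
            sel = positively_selected_sites(fit, config.pss_high, config.pss_floor)
            rows.append(
                {
                    "model": name,
                    "omega_distribution": "; ".join(
                        f"{100 * p:.2f}% sites: w={w:.3f}" for p, w in fit.model.omega_classes
                    ),
                    "lnL": round(fit.lnL, 2),
                    "n_params": fit.n_params,
                    "positively_selected_sites": "; ".join(
                        f"{s.site}{'*' if s.starred else ''}" for s in sel
                    )
                    or ("None" if any(w > 1 for w in fit.model.omegas) else "Not allowed"),
                }
            )
        for null, alt in (("M0", "M3"), ("M7", "M8")):
            if null in fits and alt in fits:
                r = likelihood_ratio_test(fits[null], fits[alt])
                lrts[f"{alt}_vs_{null}"] = {
                    "two_delta_l": round(r.two_delta_l, 2),
                    "df": r.df,
                    "p_value": r.p_value,
                }
        pd.DataFrame(rows).to_csv(out / "sitemodels.tsv", sep="\t", index=False)
        report["site_models"] = {"table": rows, "lrt": lrts}
        logger.info("site-model stage done in %.2fs", time.time() - t0)

    # --- branch models ---
    if config.run_branch_models and codon is not None and tree is not None:
        t0 = time.time()
        settings = FitSettings(seed=config.seed or 0)
        free, lrt = fit_branch_model(codon, tree, "free_ratio", settings)
        flagged = set(free.flagged_branches)
        pd.DataFrame(
            [
                {"branch": b, "omega": w, "length": free.branch_lengths[b],
                 "flagged": b in flagged}
                for b, w in free.omega_by_branch.items()
            ]
        ).to_csv(out / "branchmodel.tsv", sep="\t", index=False)
        (out / "branchmodel.nwk").write_text(
            _annotated_newick(tree, free.omega_by_branch, flagged) + "\n"
        )
        report["branch_models"] = {
            "free_ratio_lnL": round(free.lnL, 2),
            "two_delta_l": round(lrt.two_delta_l, 2),
            "df": lrt.df,
            "p_value": lrt.p_value,
            "flagged_branches": sorted(flagged),
        }
        logger.info("branch-model stage done in %.2fs", time.time() - t0)

    # --- functional divergence ---
    if config.run_diverge and groups is not None and tree is not None:
        partition = PARTITIONS[config.property_partition]
        counts = change_count_table(protein, tree, groups)
        t1 = fit_type1(counts)
        caas = type1_caas(t1, config.q_threshold)
        t2 = fit_type2(protein, tree, groups, partition)
        band = [
            int(k)
            for k, q in enumerate(t2.qk)
            if config.type2_band_low < q < config.type2_band_high
        ]
        pd.DataFrame(
            {
                "site": np.arange(protein.n_cols),
                "q_type1": t1.qk,
                "q_type2": t2.qk,
                "type2_class": t2.site_class,
            }
        ).to_csv(out / "diverge.tsv", sep="\t", index=False)
        report["functional_divergence"] = {
            "type1": {
                "theta": round(t1.theta1, 3),
                "se": round(t1.se, 3) if np.isfinite(t1.se) else None,
                "lrt": round(t1.lrt, 2),
                "p_value": t1.p_value,
                "caas": caas,
            },
            "type2": {
                "theta": round(t2.theta2, 3) if t2.defined else None,
                "se": round(t2.se, 3) if t2.defined else None,
                "p_r0": round(t2.p_r0, 3),
                "band_sites": band,
            },
        }

    # --- SDP scan ---
    if config.run_sdp and groups is not None:
        res = sdp_scan(
            protein,
            groups,
            n_shuffles=config.sdp_shuffles,
            pseudocount=config.sdp_pseudocount,
            seed=config.seed,
        )
        rows = [
            {
                "rank": rank + 1,
                "alignment_position": col,
                "mutual_information": round(float(res.mi[col]), 3),
                "z_score": round(float(res.z[col]), 3),
                "b_cutoff": round(float(res.b_curve[rank]), 3),
                "is_sdp": col in res.sdps,
                **{
                    f"residue_{lab}": r
                    for lab, r in res.group_residues.get(col, {}).items()
                },
            }
            for rank, col in enumerate(res.ranked_columns)
        ]
        pd.DataFrame(rows).to_csv(out / "sdp.tsv", sep="\t", index=False)
        report["sdp"] = {
            "cutoff_l": res.cutoff_l,
            "sdps": res.sdps,
            "table_head": rows[: max(res.cutoff_l, 5)],
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report
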