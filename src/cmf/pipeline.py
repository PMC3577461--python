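"""End-to-end analysis runs and report writing.

A run takes one alignment, filters it, scores every retained column pair
with the selected metrics, calls significant pairs and sites per metric at
the requested FDR, forms the union (CMF-significant) site set, and writes
TSV reports plus a machine-readable manifest.  All randomness flows from a
single seed; the same seed is used for both metrics' null estimation so
that a UD run with the identity matrix reproduces the U run exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .msa_io import Alignment, filter_alignment, read_msa
from .metrics import all_pair_scores
from .dcm import DoublyStochasticMatrix, read_dcm, train_dcm, write_dcm
from .significance import SignificanceResult, analyze, cmf_sites

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; every tunable of the pipeline in one place."""

    msa_path: str = None
    fdr: float = 0.01
    alpha: float = 1.0
    dcm: object = "identity"  # path, "identity", or a DoublyStochasticMatrix
    metrics: tuple = ("U", "UD")
    lambda1: float = 0.25
    lambda2: float = 0.70
    nu: int = 1000
    subinterval: tuple = (0.2, 0.8)
    percentile: float = 90.0
    strict_percentile: bool = False
    seed: int = 0
    min_id: float = 0.20
    max_id: float = 0.90
    max_cons: float = 0.95
    max_gap: float = 0.25
    min_depth: int = 125
    strict_depth: bool = False
    out_dir: str = None

    def __post_init__(self):
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class RunResult:
    config: RunConfig
    alignment: Alignment
    filter_report: object
    per_metric: dict  # metric name -> SignificanceResult
    sites: dict  # filtered-column index -> annotation dict


def _resolve_dcm(spec) -> DoublyStochasticMatrix:
    if isinstance(spec, DoublyStochasticMatrix):
        return spec
    if spec == "identity" or spec is None:
        return DoublyStochasticMatrix.identity()
    return read_dcm(spec)


def run_cmf(config: RunConfig, msa: Alignment = None) -> RunResult:
    """Execute filter -> score -> significance -> union, optionally writing
    reports to ``config.out_dir``."""
    if msa is None:
        msa = read_msa(config.msa_path)
    filtered, report = filter_alignment(
        msa,
        min_id=config.min_id,
        max_id=config.max_id,
        max_cons=config.max_cons,
        max_gap=config.max_gap,
        min_depth=config.min_depth,
        strict_depth=config.strict_depth,
    )

    dcm = _resolve_dcm(config.dcm) if "UD" in config.metrics else None
    per_metric = {}
    for metric in config.metrics:
        kwargs = {"dcm": dcm, "alpha": config.alpha} if metric == "UD" else {}
        table = all_pair_scores(filtered, metric=metric, **kwargs)
        per_metric[metric] = analyze(
            filtered,
            table,
            target_fdr=config.fdr,
            lambda1=config.lambda1,
            lambda2=config.lambda2,
            nu=config.nu,
            subinterval=config.subinterval,
            percentile=config.percentile,
            strict_percentile=config.strict_percentile,
            seed=config.seed,
            **kwargs,
        )

    if "U" in per_metric and "UD" in per_metric:
        sites = cmf_sites(per_metric["U"], per_metric["UD"])
    else:
        only = next(iter(per_metric.values()))
        sites = {
            s: {
                "u_significant": only.metric_name == "U",
                "ud_significant": only.metric_name == "UD",
                "both": False,
                "degree_u": only.connectivity.get(s, 0) if only.metric_name == "U" else 0,
                "degree_ud": only.connectivity.get(s, 0) if only.metric_name == "UD" else 0,
            }
            for s in only.significant_sites
        }

    result = RunResult(
        config=config,
        alignment=filtered,
        filter_report=report,
        per_metric=per_metric,
        sites=sites,
    )
    if config.out_dir is not None:
        write_reports(result, config.out_dir)
    return result


def write_reports(result: RunResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln = result.alignment

    def coords(col):
        return aln.col_map[col], aln.ref_residue[col]

    for metric, res in result.per_metric.items():
        rows = []
        for (i, j), score, pval in zip(res.pairs, res.scores, res.pvalues):
            if (i, j) not in res.significant_pairs:
                continue
            oi, ri = coords(i)
            oj, rj = coords(j)
            rows.append(
                dict(
                    col_i=oi, col_j=oj, ref_res_i=ri, ref_res_j=rj,
                    score=round(float(score), 6), p_value=float(pval),
                    metric=metric,
                )
            )
        pd.DataFrame(
            rows,
            columns=["col_i", "col_j", "ref_res_i", "ref_res_j", "score",
                     "p_value", "metric"],
        ).to_csv(out / f"pairs_{metric}.tsv", sep="\t", index=False)

    site_rows = []
    for site in sorted(result.sites):
        orig, ref = coords(site)
        ann = result.sites[site]
        flags = []
        if ann["u_significant"]:
            flags.append("U")
        if ann["ud_significant"]:
            flags.append("UD")
        site_rows.append(
            dict(
                ref_res=ref if ref is not None else "ref-gap",
                original_col=orig,
                degree_U=ann["degree_u"],
                degree_UD=ann["degree_ud"],
                flags="+".join(flags),
            )
        )
    pd.DataFrame(
        site_rows,
        columns=["ref_res", "original_col", "degree_U", "degree_UD", "flags"],
    ).to_csv(out / "sites.tsv", sep="\t", index=False)

    result.filter_report.to_tsv(out / "filter_report.tsv")

    with open(out / "summary.txt", "w") as fh:
        fh.write(f"n_sequences_kept\t{result.filter_report.n_kept_sequences}\n")
        fh.write(f"n_columns_kept\t{result.filter_report.n_kept_columns}\n")
        for metric, res in result.per_metric.items():
            fh.write(f"{metric}\tgamma_hat\t{res.gamma_hat:.6g}\n")
            fh.write(f"{metric}\ttau\t{res.tau:.6g}\n")
            fh.write(f"{metric}\tfdr_hat_at_tau\t{res.fdr_hat_at_tau:.6g}\n")
            fh.write(f"{metric}\tn_significant_pairs\t{len(res.significant_pairs)}\n")
            fh.write(f"{metric}\tn_significant_sites\t{len(res.significant_sites)}\n")
        fh.write(f"n_cmf_sites\t{len(result.sites)}\n")

    manifest = asdict(result.config)
    manifest["dcm"] = (
        "identity"
        if isinstance(result.config.dcm, str) or result.config.dcm is None
        else getattr(result.config.dcm, "provenance", str(result.config.dcm))
    ) if not isinstance(result.config.dcm, str) else result.config.dcm
    manifest["version"] = __version__
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def run_train(corpus_dir, fdr: float, seed: int, out_path, **train_kwargs):
    """Train a compensatory-exchange matrix from a corpus directory and
    write it with its provenance header."""
    dcm = train_dcm(corpus_dir, fdr=fdr, seed=seed, **train_kwargs)
    write_dcm(dcm, out_path)
    return dcm
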