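"""End-to-end drivers: analyze a dataset, or simulate-and-analyze demos."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import io as bio
from .cohort import (CohortSummary, TestResult, compare_cohorts,
                     summarize_cohort)
from .decompose import AnalysisParams, CellResult, assemble_cell
from .protocol import CURRENT_CLAMP, TOTAL, VOLTAGE_CLAMP, Dataset
from .simulate import GeneratorConfig, generate_cohort

log = logging.getLogger("binomatch")


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    input_path: str
    output_path: str
    params: AnalysisParams = field(default_factory=AnalysisParams)
    groups: Optional[Dict[str, str]] = None  # cell_id -> cohort label
    seed: int = 0


def analyze_dataset(dataset: Dataset,
                    params: AnalysisParams = AnalysisParams(),
                    groups: Optional[Dict[str, str]] = None
                    ) -> List[CellResult]:
    """Run the per-cell pipeline over every cell of a dataset."""
    results = []
    for cell_id in sorted(dataset.cells):
        group = groups.get(cell_id) if groups else None
        res = assemble_cell(dataset.cells[cell_id], dataset.protocol,
                            params, group=group)
        n_adapted = len(res.qc.get("adapted_conditions", []))
        if n_adapted:
            log.warning("cell %s: adaptation detected in %d conditions",
                        cell_id, n_adapted)
        if res.qc.get("undefined_pref"):
            log.warning("cell %s: undefined preference for %s", cell_id,
                        res.qc["undefined_pref"])
        log.info("cell %s analyzed (%s)", cell_id, res.clamp_mode)
        results.append(res)
    return results


def run_analyze(config: RunConfig) -> List[CellResult]:
    """Read a dataset directory, analyze it, and write result tables."""
    dataset = bio.read_dataset(config.input_path)
    results = analyze_dataset(dataset, config.params, config.groups)
    if not results:
        raise ValueError("empty cohort: no analyzable cells")
    out = Path(config.output_path)
    by_group: Dict[str, List[CellResult]] = {}
    for r in results:
        by_group.setdefault(r.group or "all", []).append(r)
    summaries = [summarize_cohort(label, cells)
                 for label, cells in sorted(by_group.items())]
    tests: Sequence[TestResult] = ()
    if set(by_group) >= {"young", "adult"}:
        _, _, tests = compare_cohorts(by_group["young"], by_group["adult"])
    bio.write_results(results, summaries, out, tests)
    qc = {r.cell_id: {"adapted_conditions":
                      [list(c) for c in
                       r.qc.get("adapted_conditions", [])],
                      "clipped_fraction_cortical":
                      r.qc.get("clipped_fraction_cortical"),
                      "undefined_pref":
                      [list(k) for k in r.qc.get("undefined_pref", [])]}
          for r in results}
    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc, fh, indent=2)
    with open(out / "provenance.json", "w") as fh:
        json.dump({"input": str(config.input_path),
                   "seed": config.seed,
                   "params": vars(config.params),
                   "dataset_provenance": dataset.provenance}, fh,
                  indent=2)
    return results


def _child_seeds(seed: int, n: int) -> List[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2 ** 31)) for s in state]


@dataclass
class DemoReport:
    """Recovered cohort metrics juxtaposed with generator truth."""

    vc_results: Dict[str, List[CellResult]]
    cc_results: Dict[str, List[CellResult]]
    summaries: Dict[str, CohortSummary]
    tests: List[TestResult]
    truth_means: Dict[str, Dict[str, float]]

    def to_text(self) -> str:
        lines = ["binomatch demo report", "=" * 60]
        for label, summary in self.summaries.items():
            lines.append(f"\ncohort: {label} (n = {summary.n_cells})")
            for name, st in sorted(summary.metrics.items()):
                truth = self.truth_means.get(label, {}).get(name)
                extra = (f"   [generator truth {truth:.2f}]"
                         if truth is not None else "")
                lines.append(f"  {name:26s} {st.mean:8.2f} "
                             f"+/- {st.sem:5.2f} (n={st.n}){extra}")
        lines.append("\nstatistical tests")
        for t in self.tests:
            lines.append(f"  {t.name:14s} {t.groups:44s} "
                         f"stat={t.statistic:7.3f} p={t.p_value:.4f} "
                         f"n={t.n}")
        return "\n".join(lines)


def run_full_demo(seed: int = 0,
                  noise_sd: Optional[float] = None,
                  n_young_vc: int = 26, n_adult_vc: int = 15,
                  n_young_cc: int = 25, n_adult_cc: int = 14,
                  params: AnalysisParams = AnalysisParams()) -> DemoReport:
    """Simulate young and adult cohorts in both clamp modes and analyze
    them end to end.

    Returns a report juxtaposing recovered cohort metrics with the
    generator's per-cohort truth means.
    """
    seeds = _child_seeds(seed, 4)
    specs = {
        ("young", VOLTAGE_CLAMP): (n_young_vc, seeds[0]),
        ("adult", VOLTAGE_CLAMP): (n_adult_vc, seeds[1]),
        ("young", CURRENT_CLAMP): (n_young_cc, seeds[2]),
        ("adult", CURRENT_CLAMP): (n_adult_cc, seeds[3]),
    }
    vc_results: Dict[str, List[CellResult]] = {}
    cc_results: Dict[str, List[CellResult]] = {}
    truth_means: Dict[str, Dict[str, float]] = {}
    for (cohort, mode), (n, s) in specs.items():
        overrides = {} if noise_sd is None else {"noise_sd": noise_sd}
        cfg = GeneratorConfig.preset(cohort, clamp_mode=mode, n_cells=n,
                                     seed=s, **overrides)
        ds, truths = generate_cohort(cfg)
        res = analyze_dataset(ds, params,
                              groups={c: cohort for c in ds.cells})
        key = cohort if mode == VOLTAGE_CLAMP else f"{cohort}_vm"
        (vc_results if mode == VOLTAGE_CLAMP else cc_results)[cohort] = res
        tm = {"delta_o_thalamic": float(np.mean(
            [t.delta_o_thalamic for t in truths]))} if truths else {}
        if mode == VOLTAGE_CLAMP:
            tm["scale_factor_contra"] = cfg.scale_factors["contra"]
            tm["scale_factor_ipsi"] = cfg.scale_factors["ipsi"]
            tm["ci_ratio_total"] = cfg.ci_ratio
        truth_means[key] = tm

    summaries = {
        "young": summarize_cohort("young", vc_results["young"]),
        "adult": summarize_cohort("adult", vc_results["adult"]),
        "young_vm": summarize_cohort("young_vm", cc_results["young"]),
        "adult_vm": summarize_cohort("adult_vm", cc_results["adult"]),
    }
    _, _, tests = compare_cohorts(vc_results["young"], vc_results["adult"])
    # Vm cohorts: between-age comparison of the inter-ocular difference
    from .cohort import ks_two_sample, ks_vs_uniform  # noqa: PLC0415
    vm_young = [r.delta_o[TOTAL] for r in cc_results["young"]
                if r.delta_o.get(TOTAL) is not None]
    vm_adult = [r.delta_o[TOTAL] for r in cc_results["adult"]
                if r.delta_o.get(TOTAL) is not None]
    if vm_young and vm_adult:
        tests.append(ks_two_sample(vm_young, vm_adult,
                                   groups="young vs adult Vm delta_o"))
        tests.append(ks_vs_uniform(vm_young,
                                   groups="young Vm delta_o vs uniform"))
    return DemoReport(vc_results=vc_results, cc_results=cc_results,
                      summaries=summaries, tests=tests,
                      truth_means=truth_means)
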