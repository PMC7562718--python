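"""End-to-end orchestration: simulate -> profile -> phase -> predict ->
validate -> dependence -> evaluate.

The pipeline runs either on synthetic data with planted ground truth or
on user-supplied FASTA/TSV inputs (via the CLI).  Every stage writes its
table to the output directory and a run log records every threshold that
was applied, so runs are auditable and byte-reproducible under a fixed
seed.

The mutant-dependence classifier is a stand-in for a full
negative-binomial differential test: per feature it applies a two-sided
exact binomial test to pooled counts against the library-size
expectation, followed by Benjamini-Hochberg correction.  It is not
equivalent to a dispersion-modelling test and the module accepts
externally computed p-values as an override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io as pio
from .degradome import DegradomeProfile, call_targets, profiles_from_records
from .phasing import PhasLocus, PhasiRNA, annotate_trigger, enumerate_phasirnas, scan_phas_loci
from .seqtools import dinucleotide_shuffle
from .srna import (
    AlignedRead,
    PositionProfile,
    SmallRNARead,
    align_exact,
    build_position_profile,
    filter_reads,
)
from .synthetic import (
    CONDITIONS,
    GroundTruth,
    RefSet,
    SyntheticConfig,
    generate_reference,
    simulate_degradome_library,
    simulate_srna_library,
)
from .targets import DuplexAlignment, PenaltyScheme, iter_candidates_concat


@dataclass
class PipelineConfig:
    """Thresholds and switches of a pipeline run (synthetic mode)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    periods: tuple[int, ...] = (21, 24)
    phase_score_threshold: float = 15.0
    min_phased_positions: int = 4
    max_mispair_score: float = 3.5
    max_bulges: int = 2
    min_tags: float = 4.0
    min_site_fraction: float = 0.10
    fold_threshold: float = 2.0
    fdr_threshold: float = 0.05
    multimap_policy: str = "count-all"
    degradome_average: str = "occupied"
    decoy_check: bool = True
    threshold_sweep: tuple[float, ...] = (5.0, 15.0, 30.0)

    def scheme(self) -> PenaltyScheme:
        return PenaltyScheme(max_score=self.max_mispair_score, max_bulges=self.max_bulges)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", {})
        if "triggers" in syn:
            syn["triggers"] = {
                int(k): tuple(v) for k, v in syn["triggers"].items()
            }
        if "transcript_len_range" in syn:
            syn["transcript_len_range"] = tuple(syn["transcript_len_range"])
        cfg = cls(synthetic=SyntheticConfig(**syn))
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            if isinstance(getattr(cfg, key), tuple):
                val = tuple(val)
            setattr(cfg, key, val)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["synthetic"]["triggers"] = {
            k: list(v) for k, v in d["synthetic"]["triggers"].items()
        }
        d["synthetic"]["transcript_len_range"] = list(
            d["synthetic"]["transcript_len_range"]
        )
        d["periods"] = list(d["periods"])
        d["threshold_sweep"] = list(d["threshold_sweep"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class DependenceCall:
    name: str
    mean_rpm_wt: float
    mean_rpm_mut: float
    fold_change: float
    p_value: float
    fdr: float
    dependent: bool


def classify_dependence(
    counts_wt: np.ndarray,
    counts_mut: np.ndarray,
    lib_sizes_wt: Sequence[float],
    lib_sizes_mut: Sequence[float],
    names: Sequence[str] | None = None,
    fold_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    p_values: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Flag features depleted in the mutant condition.

    ``counts_wt``/``counts_mut`` are (features x replicates) raw counts.
    A feature is "dependent" iff its wild-type/mutant fold change of mean
    RPM is >= fold_threshold and its BH-adjusted p-value is
    <= fdr_threshold.  Features with zero counts in both conditions are
    skipped.  Externally computed per-feature p-values (same feature
    order, before skipping) may be passed to replace the built-in test.
    """
    counts_wt = np.atleast_2d(np.asarray(counts_wt, dtype=float))
    counts_mut = np.atleast_2d(np.asarray(counts_mut, dtype=float))
    if counts_wt.shape[1] < 2 or counts_mut.shape[1] < 2:
        raise ValueError("at least two replicates per condition are required")
    lw = np.asarray(lib_sizes_wt, dtype=float)
    lm = np.asarray(lib_sizes_mut, dtype=float)
    if (lw <= 0).any() or (lm <= 0).any():
        raise ValueError("library sizes must be positive")
    n_feat = counts_wt.shape[0]
    if names is None:
        names = [f"feature{i + 1}" for i in range(n_feat)]
    keep = (counts_wt.sum(axis=1) + counts_mut.sum(axis=1)) > 0
    p0 = lw.sum() / (lw.sum() + lm.sum())
    rows = []
    pvals = []
    for i in np.nonzero(keep)[0]:
        x = counts_wt[i].sum()
        y = counts_mut[i].sum()
        rpm_wt = float(np.mean(counts_wt[i] / lw) * 1e6)
        rpm_mut = float(np.mean(counts_mut[i] / lm) * 1e6)
        fold = rpm_wt / rpm_mut if rpm_mut > 0 else float("inf")
        if p_values is not None:
            p = float(p_values[i])
        else:
            p = stats.binomtest(int(round(x)), int(round(x + y)), p0).pvalue
        pvals.append(p)
        rows.append([names[i], rpm_wt, rpm_mut, fold, p])
    if not rows:
        return pd.DataFrame(
            columns=[
                "name",
                "mean_rpm_wt",
                "mean_rpm_mut",
                "fold_change",
                "p_value",
                "fdr",
                "dependent",
            ]
        )
    fdr = stats.false_discovery_control(np.array(pvals))
    df = pd.DataFrame(
        rows, columns=["name", "mean_rpm_wt", "mean_rpm_mut", "fold_change", "p_value"]
    )
    df["fdr"] = fdr
    df["dependent"] = (df["fold_change"] >= fold_threshold) & (
        df["fdr"] <= fdr_threshold
    )
    return df


@dataclass
class RecoveryReport:
    """Recovery of planted loci and targets by a synthetic run."""

    locus_tp: int = 0
    locus_fp: int = 0
    locus_fn: int = 0
    target_tp: int = 0
    target_fp: int = 0
    target_fn: int = 0
    decoy_candidates: int | None = None
    decoy_validated: int | None = None
    threshold_sweep: list[dict] = field(default_factory=list)

    @property
    def locus_precision(self) -> float:
        d = self.locus_tp + self.locus_fp
        return self.locus_tp / d if d else float("nan")

    @property
    def locus_recall(self) -> float:
        d = self.locus_tp + self.locus_fn
        return self.locus_tp / d if d else float("nan")

    @property
    def target_precision(self) -> float:
        d = self.target_tp + self.target_fp
        return self.target_tp / d if d else float("nan")

    @property
    def target_recall(self) -> float:
        d = self.target_tp + self.target_fn
        return self.target_tp / d if d else float("nan")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            locus_precision=self.locus_precision,
            locus_recall=self.locus_recall,
            target_precision=self.target_precision,
            target_recall=self.target_recall,
        )
        return d


def match_locus(called: PhasLocus, planted) -> bool:
    """A called locus matches a planted one by reference, period, register
    and span overlap."""
    if called.reference_id != planted.ref_id or called.period != planted.period:
        return False
    if called.register != planted.register:
        return False
    span_lo = min(planted.plus_positions + planted.minus_positions)
    span_hi = max(planted.plus_positions + planted.minus_positions) + planted.period
    return called.start < span_hi and called.end > span_lo


def evaluate_against_truth(
    loci: Sequence[PhasLocus],
    validated: pd.DataFrame,
    truth: GroundTruth,
    decoy_candidates: int | None = None,
    decoy_validated: int | None = None,
) -> RecoveryReport:
    """Match calls to planted truth: loci by register + overlap, targets by
    exact (transcript, cleavage site)."""
    report = RecoveryReport(
        decoy_candidates=decoy_candidates, decoy_validated=decoy_validated
    )
    matched_called: set[int] = set()
    for planted in truth.loci:
        hit = False
        for idx, called in enumerate(loci):
            if match_locus(called, planted):
                matched_called.add(idx)
                hit = True
        if hit:
            report.locus_tp += 1
        else:
            report.locus_fn += 1
    report.locus_fp = len(loci) - len(matched_called)
    planted_sites = {
        (t.transcript_id, t.cleavage_site) for t in truth.targets if t.validatable
    }
    called_sites = set()
    if len(validated):
        called_sites = {
            (str(r.transcript_id), int(r.site))
            for r in validated[validated["validated"]].itertuples(index=False)
        }
    report.target_tp = len(planted_sites & called_sites)
    report.target_fn = len(planted_sites - called_sites)
    report.target_fp = len(called_sites - planted_sites)
    return report


@dataclass
class PipelineResult:
    config: PipelineConfig
    refs: RefSet
    truth: GroundTruth
    loci: list[PhasLocus]
    phasirnas: list[PhasiRNA]
    candidates: list[DuplexAlignment]
    targets: pd.DataFrame
    dependence: pd.DataFrame
    recovery: RecoveryReport | None
    outdir: Path | None


def _library_name(condition: str, rep: int) -> str:
    return f"{condition}_rep{rep}"


def build_profiles(
    libraries: Mapping[tuple[str, int], Mapping[str, int]],
    reference: Mapping[str, str],
    policy: str = "count-all",
) -> tuple[PositionProfile, dict[str, PositionProfile]]:
    """Map the union of library reads once and build pooled + per-library
    position profiles."""
    pooled_counts: dict[str, int] = {}
    for lib in libraries.values():
        for seq, c in lib.items():
            pooled_counts[seq] = pooled_counts.get(seq, 0) + c
    union = filter_reads([SmallRNARead(s, c) for s, c in pooled_counts.items()])
    aligned, _unmapped = align_exact(union, reference, policy=policy)
    pooled = build_position_profile(aligned)
    placements: dict[str, list[AlignedRead]] = {}
    for a in aligned:
        placements.setdefault(a.sequence, []).append(a)
    per_lib: dict[str, PositionProfile] = {}
    for (condition, rep), lib in libraries.items():
        prof = PositionProfile()
        for seq, c in lib.items():
            for a in placements.get(seq, ()):
                prof.add(a.reference_id, a.strand, a.start, a.length, c * a.weight)
                prof.library_total += c / a.n_placements
        per_lib[_library_name(condition, rep)] = prof
    return pooled, per_lib


def candidates_table(candidates: Sequence[DuplexAlignment]) -> pd.DataFrame:
    rows = [
        {
            "srna_id": a.srna_id,
            "srna_seq": a.srna_sequence,
            "transcript_id": a.target_id,
            "site_start": a.target_start + 1,
            "site_end": a.target_end,
            "mispair_score": a.score,
            "cleavage_site": a.cleavage_site,
            "duplex": a.states,
        }
        for a in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "srna_id",
            "srna_seq",
            "transcript_id",
            "site_start",
            "site_end",
            "mispair_score",
            "cleavage_site",
            "duplex",
        ],
    )


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute every stage on synthetic data and (optionally) write the
    full report bundle to ``outdir``."""
    syn = config.synthetic
    refs, truth = generate_reference(syn)
    libraries = simulate_srna_library(refs, truth, syn)
    tags = simulate_degradome_library(refs, truth, syn)
    reference = refs.all()
    ref_lengths = {k: len(v) for k, v in reference.items()}
    pooled, per_lib = build_profiles(libraries, reference, config.multimap_policy)

    loci: list[PhasLocus] = []
    for period in config.periods:
        loci.extend(
            scan_phas_loci(
                pooled,
                period,
                score_threshold=config.phase_score_threshold,
                min_phased_positions=config.min_phased_positions,
                reference_lengths=ref_lengths,
            )
        )
    trigger_map = {name: seq for name, seq in syn.triggers.values()}
    phasirnas: list[PhasiRNA] = []
    scheme = config.scheme()
    for locus in loci:
        phasirnas.extend(enumerate_phasirnas(locus, pooled, reference, per_lib))
        locus.trigger = annotate_trigger(
            locus,
            reference[locus.reference_id],
            trigger_map,
            max_score=config.max_mispair_score,
            scheme=scheme,
        )

    srna_pool: dict[str, str] = {}
    seen_seqs: set[str] = set()
    for x in phasirnas:
        if x.sequence not in seen_seqs:
            seen_seqs.add(x.sequence)
            srna_pool[x.name] = x.sequence
    candidates = list(iter_candidates_concat(srna_pool, refs.transcripts, scheme))

    profiles = profiles_from_records(
        tags, {k: len(v) for k, v in refs.transcripts.items()}
    )
    degradome_total = float(sum(t.count for t in tags))
    targets = call_targets(
        candidates,
        profiles,
        library_total=degradome_total or None,
        min_tags=config.min_tags,
        min_fraction=config.min_site_fraction,
        average=config.degradome_average,
    )

    dependence = _dependence_stage(phasirnas, per_lib, syn, config)

    recovery = _evaluate_stage(
        config, refs, truth, loci, targets, profiles, degradome_total, pooled, ref_lengths
    )

    result = PipelineResult(
        config, refs, truth, loci, phasirnas, candidates, targets, dependence,
        recovery, Path(outdir) if outdir else None,
    )
    if outdir is not None:
        _write_bundle(result, libraries, tags, pooled)
    return result


def _dependence_stage(phasirnas, per_lib, syn, config) -> pd.DataFrame:
    if not phasirnas:
        return classify_dependence(
            np.zeros((0, max(syn.replicates, 2))),
            np.zeros((0, max(syn.replicates, 2))),
            [1.0] * max(syn.replicates, 2),
            [1.0] * max(syn.replicates, 2),
        )
    wt_names = [_library_name("wildtype", r) for r in range(1, syn.replicates + 1)]
    mut_names = [_library_name("mutant", r) for r in range(1, syn.replicates + 1)]
    counts_wt = np.array([[x.abundances.get(n, 0.0) for n in wt_names] for x in phasirnas])
    counts_mut = np.array(
        [[x.abundances.get(n, 0.0) for n in mut_names] for x in phasirnas]
    )
    lib_wt = [per_lib[n].library_total for n in wt_names]
    lib_mut = [per_lib[n].library_total for n in mut_names]
    return classify_dependence(
        counts_wt,
        counts_mut,
        lib_wt,
        lib_mut,
        names=[x.name for x in phasirnas],
        fold_threshold=config.fold_threshold,
        fdr_threshold=config.fdr_threshold,
    )


def _evaluate_stage(
    config, refs, truth, loci, targets, profiles, degradome_total, pooled, ref_lengths
) -> RecoveryReport:
    decoy_candidates = decoy_validated = None
    if config.decoy_check and truth.targets:
        rng = np.random.default_rng([config.synthetic.seed, 3])
        decoys = {
            f"decoy{i + 1}": dinucleotide_shuffle(t.srna_sequence, rng)
            for i, t in enumerate(truth.targets)
        }
        dec_cands = list(
            iter_candidates_concat(decoys, refs.transcripts, config.scheme())
        )
        dec_calls = call_targets(
            dec_cands,
            profiles,
            library_total=degradome_total or None,
            min_tags=config.min_tags,
            min_fraction=config.min_site_fraction,
            average=config.degradome_average,
        )
        decoy_candidates = len(dec_cands)
        decoy_validated = int(dec_calls["validated"].sum()) if len(dec_calls) else 0
    report = evaluate_against_truth(
        loci, targets, truth, decoy_candidates, decoy_validated
    )
    for thr in config.threshold_sweep:
        sweep_loci: list[PhasLocus] = []
        for period in config.periods:
            sweep_loci.extend(
                scan_phas_loci(
                    pooled,
                    period,
                    score_threshold=thr,
                    min_phased_positions=config.min_phased_positions,
                    reference_lengths=ref_lengths,
                )
            )
        sub = evaluate_against_truth(sweep_loci, pd.DataFrame(), truth)
        report.threshold_sweep.append(
            {
                "score_threshold": thr,
                "n_loci": len(sweep_loci),
                "locus_recall": sub.locus_recall,
                "locus_precision": sub.locus_precision,
            }
        )
    return report


def _write_bundle(result: PipelineResult, libraries, tags, pooled) -> None:
    out = result.outdir
    out.mkdir(parents=True, exist_ok=True)
    pio.write_fasta(out / "reference.fasta", result.refs.all())
    pio.write_fasta(out / "transcripts.fasta", result.refs.transcripts)
    for (condition, rep), lib in libraries.items():
        pio.write_collapsed_fasta(
            out / f"srna_{_library_name(condition, rep)}.fasta", lib
        )
    pio.write_tags_tsv(out / "degradome_tags.tsv", tags)
    pio.write_truth(out, result.truth)
    pio.write_profile_tsv(out / "position_profile.tsv", pooled)
    pio.write_loci_gff3(out / "loci.gff3", result.loci)
    pio.loci_table(result.loci).to_csv(out / "loci.tsv", sep="\t", index=False)
    pio.phasirna_table(result.phasirnas).to_csv(
        out / "phasirnas.tsv", sep="\t", index=False
    )
    pio.write_fasta(
        out / "phasirnas.fasta", {x.name: x.sequence for x in result.phasirnas}
    )
    candidates_table(result.candidates).to_csv(
        out / "candidate_targets.tsv", sep="\t", index=False
    )
    result.targets.to_csv(out / "validated_targets.tsv", sep="\t", index=False)
    result.dependence.to_csv(out / "dependence.tsv", sep="\t", index=False)
    if result.recovery is not None:
        import json

        with open(out / "recovery.json", "w") as fh:
            json.dump(result.recovery.to_dict(), fh, indent=2, sort_keys=True)
    _write_run_log(out, result)


def _write_run_log(out: Path, result: PipelineResult) -> None:
    from . import __version__

    cfg = result.config
    log = {
        "package": f"phasiscan {__version__}",
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": cfg.synthetic.seed,
        "thresholds": {
            "phase_score": cfg.phase_score_threshold,
            "min_phased_positions": cfg.min_phased_positions,
            "max_mispair_score": cfg.max_mispair_score,
            "min_tags_at_site": cfg.min_tags,
            "min_site_fraction": cfg.min_site_fraction,
            "fold_change": cfg.fold_threshold,
            "fdr": cfg.fdr_threshold,
        },
        "multimap_policy": cfg.multimap_policy,
        "degradome_average": cfg.degradome_average,
        "n_loci": len(result.loci),
        "n_phasirnas": len(result.phasirnas),
        "n_candidates": len(result.candidates),
        "n_validated_targets": int(result.targets["validated"].sum())
        if len(result.targets)
        else 0,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
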