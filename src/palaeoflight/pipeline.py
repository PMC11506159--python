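"""End-to-end analysis pipeline: generate/load -> measure -> model -> compare.

Orchestrates the synthetic-cohort generator (or on-disk cohort files), the
outline and flight-performance measurements, the discrete-character
disparity analyses and the comparative statistics into one machine-readable
:class:`AnalysisReport`, reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from palaeoflight import __version__ as _pkg_version
from palaeoflight import comparative, disparity, flight, synthetic, wing_geometry

logger = logging.getLogger("palaeoflight")


class PipelineError(RuntimeError):
    """Raised when the pipeline cannot produce a complete report."""


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serializable)."""

    mode: str = "synthetic"                 # synthetic | files
    groups: dict = field(default_factory=lambda: {"early": 200, "late": 200})
    spec_overrides: dict = field(default_factory=dict)   # per-group CohortSpec overrides
    # outline analysis
    n_harmonics: int = 7
    n_outline_points: int = 300
    # character / disparity analysis
    n_chars: int = 86
    missing_frac: float = 0.2
    divergence: float = 0.6
    char_within_noise: dict = field(
        default_factory=lambda: {"early": 0.25, "late": 0.10})
    distance_method: str = "MORD"
    pcoa_correction: str = "cailliez"
    n_boot: int = 500
    n_perm: int = 999
    # flight model
    wl_area: str = "combined_pair"          # combined_pair | forewing_pair
    shape_factors: dict = field(default_factory=dict)    # per-group k_pt/k_mt/k_ab
    # file mode inputs
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class TaxonRecord:
    """Metadata row for one taxon (used by the diversity tally and file mode)."""

    taxon_id: str
    group: str
    interval: str
    files: dict = field(default_factory=dict)


@dataclass
class AnalysisReport:
    """Machine-readable result of one pipeline run."""

    group_medians: dict          # group -> trait -> {median, q1, q3}
    percent_differences: dict    # trait -> % (early -> late)
    speed_ratio: float           # U_late / U_early from median WL
    welch: dict                  # trait -> welch_t result
    pearson: dict                # group -> {r, p} for log AR ~ log b
    ancova: dict                 # interaction F/p + per-group slopes
    disparity: dict              # group -> metric -> {estimate, ci_low, ci_high}
    disparity_welch: dict        # metric -> Welch p on bootstrap distributions
    permanova: dict
    harmonic_power_at_n: float   # mean cumulative power at n_harmonics
    shape_pca_variance: list     # variance-explained, first axes
    diversity: dict              # interval -> group -> count
    warnings: list
    provenance: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "AnalysisReport":
        is_path = isinstance(source, pathlib.Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{"))
        if is_path:
            data = json.loads(pathlib.Path(source).read_text())
        else:
            data = json.loads(source)
        return cls(**data)

    def to_csv(self, path):
        """Flat (key, value) CSV export of the scalar report content."""
        rows = []

        def walk(prefix, obj):
            if isinstance(obj, dict):
                for k, v in obj.items():
                    walk(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(f"{prefix}[{i}]", v)
            else:
                rows.append({"key": prefix, "value": obj})

        walk("", dataclasses.asdict(self))
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Diversity tally
# ---------------------------------------------------------------------------


def diversity_tally(records) -> dict:
    """Taxon counts per stratigraphic interval per group.

    Accepts :class:`TaxonRecord` or :class:`~palaeoflight.synthetic.SyntheticTaxon`
    (anything with ``group`` and ``interval``).  Unknown interval labels
    raise, listing the offending records.
    """
    bad = [getattr(r, "taxon_id", "?") for r in records
           if r.interval not in synthetic.INTERVALS]
    if bad:
        raise PipelineError(f"unknown stratigraphic interval for: {bad}")
    tally: dict = {}
    for r in records:
        tally.setdefault(r.interval, {}).setdefault(r.group, 0)
        tally[r.interval][r.group] += 1
    return tally


# ---------------------------------------------------------------------------
# Cohort measurement
# ---------------------------------------------------------------------------

TRAITS = ("WL", "AR_forewing", "AR_combined", "m_star_muscle",
          "S_costal", "S_clavus")


def measure_cohort(taxa, config: PipelineConfig) -> pd.DataFrame:
    """Per-taxon trait table from wing outlines and body measurements."""
    rows = []
    for t in taxa:
        rot, trans = synthetic.default_hindwing_placement(t.forewing, t.hindwing)
        combined = wing_geometry.combine_wings(t.forewing, t.hindwing, rot, trans)
        m = flight.taxon_flight_metrics(
            t.forewing, combined, t.body,
            shape_factors=config.shape_factors.get(t.group),
            wl_area=config.wl_area)
        m.update(wing_geometry.region_area_proportions(t.forewing))
        m.update({"taxon_id": t.taxon_id, "group": t.group,
                  "interval": t.interval,
                  "combined_multi_part": combined.multi_part})
        rows.append(m)
    return pd.DataFrame(rows)


def _median_iqr(x) -> dict:
    q1, med, q3 = np.percentile(np.asarray(x, float), [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


# ---------------------------------------------------------------------------
# File-mode loading
# ---------------------------------------------------------------------------


def load_cohort(paths: dict):
    """Load a cohort written by :func:`palaeoflight.synthetic.write_cohort`.

    ``paths`` needs keys ``forewings`` and ``hindwings`` (TPS files),
    ``bodies`` and ``taxa`` (CSV).  All inputs are validated before any
    analysis; missing files are reported together and no partial cohort is
    returned.
    """
    required = ("forewings", "hindwings", "bodies", "taxa")
    missing = [k for k in required
               if k not in paths or not pathlib.Path(paths[k]).exists()]
    if missing:
        raise PipelineError(f"missing input files: {missing}")
    fw = wing_geometry.read_tps(paths["forewings"])
    hw = wing_geometry.read_tps(paths["hindwings"])
    outlines_dir = pathlib.Path(paths["forewings"]).parent / "outlines"
    for tid, outline in fw.items():
        for name in wing_geometry.REGION_NAMES:
            reg_path = outlines_dir / f"{tid}_region_{name}.csv"
            if reg_path.exists():
                outline.regions[name] = wing_geometry.read_xy_csv(reg_path)
    bodies = pd.read_csv(paths["bodies"]).set_index("taxon_id")
    meta = pd.read_csv(paths["taxa"]).set_index("taxon_id")
    problems = []
    taxa = []
    for tid, row in meta.iterrows():
        if tid not in fw:
            problems.append(f"{tid}: no forewing outline")
            continue
        if tid not in hw:
            problems.append(f"{tid}: no hindwing outline")
            continue
        if tid not in bodies.index:
            problems.append(f"{tid}: no body measurements")
            continue
        b = bodies.loc[tid]
        taxa.append(synthetic.SyntheticTaxon(
            taxon_id=str(tid), group=str(row["group"]),
            forewing=fw[tid], hindwing=hw[tid],
            body=flight.BodyMeasurements(
                w_thorax=float(b["w_thorax_mm"]), l_pt=float(b["l_pt_mm"]),
                l_mt=float(b["l_mt_mm"]), l_abdomen=float(b["l_abdomen_mm"]),
                group=str(row["group"])),
            interval=str(row["interval"])))
    if problems:
        raise PipelineError("incomplete cohort, refusing partial report: "
                            + "; ".join(problems))
    return taxa


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig | None = None,
                 seed: int = 0) -> AnalysisReport:
    """Execute every analysis stage and assemble the report.

    Deterministic given (config, seed): all random streams are spawned from
    the single seed.
    """
    config = config or PipelineConfig()
    warnings: list = []
    ss = np.random.SeedSequence(seed)
    seed_cohort, seed_chars, seed_boot, seed_perm = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4))

    if config.mode == "synthetic":
        specs = [synthetic.default_cohort_spec(
            g, n, **config.spec_overrides.get(g, {}))
            for g, n in config.groups.items()]
        taxa = synthetic.generate_cohort(specs, seed=seed_cohort)
    elif config.mode == "files":
        taxa = load_cohort(config.paths)
    else:
        raise PipelineError(f"unknown mode {config.mode!r}")

    df = measure_cohort(taxa, config)
    if df["combined_multi_part"].any():
        warnings.append(f"{int(df.combined_multi_part.sum())} disjoint "
                        "combined-wing unions")
    groups = [g for g in ("early", "late", "dunstaniid")
              if g in set(df["group"])]
    medians = {g: {tr: _median_iqr(df.loc[df.group == g, tr])
                   for tr in TRAITS if tr in df}
               for g in groups}

    pct, welch, speed_ratio = {}, {}, float("nan")
    if "early" in groups and "late" in groups:
        early = df[df.group == "early"]
        late = df[df.group == "late"]
        for tr in ("WL", "AR_forewing", "AR_combined", "m_star_muscle",
                   "S_costal", "S_clavus"):
            pct[tr] = comparative.median_percent_difference(
                early[tr], late[tr], digits=0)
            welch[tr] = comparative.welch_t(early[tr], late[tr])
        speed_ratio = flight.relative_speed_ratio(
            float(early["WL"].median()), float(late["WL"].median()))

    # allometry: log AR_forewing ~ log wingspan
    pearson, ancova = {}, {}
    for g in groups:
        sub = df[df.group == g]
        if len(sub) >= 3:
            pearson[g] = comparative.pearson_cor(
                np.log(sub["b"]), np.log(sub["AR_forewing"]))
    if "early" in groups and "late" in groups:
        sub = df[df.group.isin(["early", "late"])]
        fit = comparative.ancova_interaction(
            np.log(sub["b"]), np.log(sub["AR_forewing"]), sub["group"].to_numpy())
        ancova = {"interaction_F": fit.interaction_F,
                  "interaction_p": fit.interaction_p,
                  "slopes": fit.slopes, "residual_sd": fit.residual_sd}

    # forewing shape: EFD, harmonic power, shape PCA
    series = [wing_geometry.efd_forward(
        t.forewing, config.n_harmonics, config.n_outline_points)
        for t in taxa]
    power_series = [wing_geometry.efd_forward(
        t.forewing, max(3 * config.n_harmonics, 21), config.n_outline_points,
        normalize=False) for t in taxa[:50]]
    mean_power = float(np.mean([
        wing_geometry.harmonic_power(h)[config.n_harmonics - 1]
        for h in power_series]))
    space = wing_geometry.shape_pca(series)
    pca_var = [float(v) for v in space.variance_ratio[:3]]

    # discrete characters -> distances -> morphospace -> disparity
    labels = [t.group for t in taxa]
    cm = synthetic.generate_character_matrix(
        labels, n_chars=config.n_chars, missing_frac=config.missing_frac,
        divergence=config.divergence, seed=seed_chars,
        within_noise=config.char_within_noise)
    dm = disparity.pairwise_distance(cm, config.distance_method)
    n_masked = int(np.isnan(dm.values).sum() // 2)
    if n_masked:
        warnings.append(f"{n_masked} incomparable taxon pairs imputed")
        dm = disparity.impute_masked(dm)
    ordn = disparity.pcoa(dm, correction=config.pcoa_correction)
    coords = ordn.coordinates
    disp, disp_boot = {}, {}
    for g in groups:
        mask = np.array([lab == g for lab in labels])
        disp[g] = {}
        disp_boot[g] = {}
        for metric in ("SOV", "SOR", "MDC"):
            summ = disparity.bootstrap_disparity(
                coords[mask], metric, n_boot=config.n_boot,
                seed=seed_boot, group=g)
            disp[g][metric] = {"estimate": summ.estimate,
                               "ci_low": summ.ci_low, "ci_high": summ.ci_high}
            disp_boot[g][metric] = summ.bootstrap
    disparity_welch = {}
    if "early" in groups and "late" in groups:
        for metric in ("SOV", "SOR", "MDC"):
            res = comparative.welch_t(disp_boot["early"][metric],
                                      disp_boot["late"][metric])
            disparity_welch[metric] = res["p"]
    perm = disparity.permanova(dm, labels, n_perm=config.n_perm,
                               seed=seed_perm)

    report = AnalysisReport(
        group_medians=medians,
        percent_differences=pct,
        speed_ratio=float(speed_ratio),
        welch={k: {kk: (None if isinstance(vv, float) and not np.isfinite(vv)
                        else vv) for kk, vv in v.items()}
               for k, v in welch.items()},
        pearson=pearson,
        ancova=ancova,
        disparity=disp,
        disparity_welch=disparity_welch,
        permanova=perm,
        harmonic_power_at_n=mean_power,
        shape_pca_variance=pca_var,
        diversity=diversity_tally(taxa),
        warnings=warnings,
        provenance={"seed": int(seed), "config_digest": config.digest(),
                    "mode": config.mode, "package_version": _pkg_version,
                    "n_taxa": len(taxa)},
    )
    logger.info("pipeline complete: %d taxa, config %s, seed %d",
                len(taxa), config.digest(), seed)
    return report
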