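"""End-to-end orchestration: simulate → measure → analyze → cluster → report.

The per-scute table is the interchange format between stages, so a run
can start from a synthetic batch, from labeled volumes, or directly from
a deposited per-scute table.  The statistical sequence mirrors the
carapace study design: scaling fits of carapace dimensions and scute
count against SA; curvature scaling and normalization; edge/flat
classification by normalized CGS; per-region scute-dimension scaling
with interaction tests; shape frequencies; and PCA + Ward clustering of
the normalized scute variables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synthetic import CarapaceSpec, synthesize_carapace
from .morphometrics import measure_specimen, MISSING_FLAG, SpecimenSummary
from .allometry import (fit_loglog, fit_scute_count, normalize_by_sa,
                        residuals_by_geometry, region_interaction_test)
from .regions import classify_region, shape_frequencies, CGS_EDGE_THRESHOLD
from .clustering import (prepare_matrix, run_pca, hierarchical_clusters,
                         cluster_summaries, correlation_panel,
                         CLUSTER_VARIABLES)
from . import io as btio

log = logging.getLogger("boxtess")

#: scute variables regressed per region (Table-1 style)
SCUTE_DIMENSIONS = ["volume", "area", "width", "thickness", "aspect_ratio"]

#: per-geometry-class carapace proportions (height, width as fractions of
#: length): elliptic carapaces are relatively high and narrow, tetragonal
#: ones low and wide, triangular in between
CLASS_PROPORTIONS = {
    "elliptic": (0.60, 0.40),
    "triangular": (0.55, 0.47),
    "tetragonal": (0.50, 0.45),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one input mode)."""

    mode: str = "synthetic"          # synthetic | label_volume | scute_table
    out_dir: str = "results/run"
    seed: int = 42
    # synthetic mode
    n_specimens: int = 13
    geometry_classes: tuple = ("elliptic", "triangular", "tetragonal")
    size_span: float = 4.0
    base_length_mm: float = 42.0
    # label_volume mode
    volume_paths: tuple = ()
    volume_geometry: tuple = ()
    # scute_table mode
    table_path: str = ""
    sa_column: str = "surface_area"
    summaries_path: str = ""
    column_mapping: dict = field(default_factory=dict)
    # analysis options
    cgs_threshold: float = CGS_EDGE_THRESHOLD
    mad_factor: float = 8.0
    min_contact: int = 1
    k_clusters: int = 5
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("synthetic", "label_volume", "scute_table"):
            raise ValueError(f"unknown input mode {self.mode!r}")


def simulate_batch(seed: int, n_specimens: int = 13,
                   geometry_classes=("tetragonal",),
                   size_span: float = 4.0,
                   base_length_mm: float = 42.0,
                   **spec_overrides) -> list[CarapaceSpec]:
    """Specs for a batch of carapaces spanning ``size_span`` in length.

    Scute counts are drawn uniformly from the interspecific range
    398–535; carapace proportions follow the geometry class with 5%
    lognormal jitter; voxel size and shell thickness scale with length
    so that relative resolution is constant across the batch.
    """
    rng = np.random.default_rng(seed)
    lengths = np.geomspace(base_length_mm, base_length_mm * size_span,
                           n_specimens)
    specs = []
    for i, L in enumerate(lengths):
        gcls = geometry_classes[i % len(geometry_classes)]
        h_f, w_f = CLASS_PROPORTIONS[gcls]
        h = L * h_f * float(np.exp(rng.normal(0, 0.05)))
        w = L * w_f * float(np.exp(rng.normal(0, 0.05)))
        # six scutes become openings: draw so the measured count
        # lands in the interspecific range 398-535
        n_scutes = int(rng.integers(404, 542))
        kwargs = dict(
            geometry_class=gcls, length_mm=float(L), height_mm=h,
            width_mm=w, n_scutes=n_scutes, n_openings=6,
            base_thickness_mm=L / 60.0, voxel_mm=L / 143.0,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        kwargs.update(spec_overrides)
        specs.append(CarapaceSpec(**kwargs))
    return specs


def measure_batch(specs, keep_partitions: bool = False,
                  min_contact: int = 1):
    """Synthesize and measure a batch of specs end-to-end.

    Returns (records, summaries, extras): the concatenated per-scute
    table, the specimen-summary table, and (with ``keep_partitions``)
    per-specimen dicts holding the partition and planted types.
    """
    all_records, summaries, extras = [], [], []
    for i, spec in enumerate(specs):
        sid = f"synthetic_{i:02d}"
        partition, volume = synthesize_carapace(spec)
        rec, summ = measure_specimen(volume, specimen_id=sid,
                                     geometry_class=spec.geometry_class,
                                     min_contact=min_contact,
                                     axes_hint=np.array([0.0, 0.0, 1.0]))
        log.info("measured %s: %d scutes, SA %.0f mm^2", sid, len(rec),
                 summ.surface_area)
        all_records.append(rec)
        summaries.append(summ)
        if keep_partitions:
            extras.append({"spec": spec, "partition": partition,
                           "planted": partition.planted_type,
                           "specimen_id": sid})
    records = pd.concat(all_records, ignore_index=True)
    summary_df = pd.DataFrame([asdict_summary(s) for s in summaries])
    return records, summary_df, extras


def asdict_summary(s: SpecimenSummary) -> dict:
    return {"specimen": s.specimen_id, "surface_area": s.surface_area,
            "length": s.length, "height": s.height, "width": s.width,
            "n_scutes": s.n_scutes, "geometry_class": s.geometry_class}


# ---------------------------------------------------------------------------
# the statistical core shared by scripts, tests and acceptance

def analyze_batch(records: pd.DataFrame, summaries: pd.DataFrame,
                  cgs_threshold: float = CGS_EDGE_THRESHOLD,
                  mad_factor: float = 8.0, k_clusters: int = 5) -> dict:
    """Full statistical analysis of a measured batch.

    Returns a dict with scaling fits (carapace dimensions, scute count,
    curvatures, per-region scute dimensions), interaction-test p-values,
    region labels, shape-frequency table, the prepared matrix, PCA and
    cluster model.
    """
    summaries = summaries.set_index("specimen", drop=False)
    sa = summaries["surface_area"]
    sa_by_specimen = sa.to_dict()
    ids = list(summaries.index)

    out: dict = {"sa_by_specimen": sa_by_specimen}

    # 1) carapace dimensions and scute count vs SA
    dim_fits = {}
    for var in ("length", "height", "width"):
        dim_fits[var] = fit_loglog(sa.to_numpy(),
                                   summaries[var].to_numpy(),
                                   variable=var, specimen_ids=ids)
    count_fit = fit_scute_count(sa.to_numpy(),
                                summaries["n_scutes"].to_numpy(),
                                specimen_ids=ids)
    out["dimension_fits"] = dim_fits
    out["count_fit"] = count_fit

    # 2) curvature scaling (per-specimen medians, all scutes) and
    #    normalization for the edge/flat split
    med = records.groupby("specimen")[["cgs", "cms"]].median()
    med = med.loc[ids]
    curv_fits = {
        "cgs": fit_loglog(sa.to_numpy(), med["cgs"].to_numpy(),
                          variable="cgs", specimen_ids=ids),
        "cms": fit_loglog(sa.to_numpy(), med["cms"].to_numpy(),
                          variable="cms", specimen_ids=ids),
    }
    out["curvature_fits"] = curv_fits

    rec = records.copy()
    rec_sa = rec["specimen"].map(sa_by_specimen).to_numpy(dtype=float)
    rec["normalized_cgs"] = normalize_by_sa(rec["cgs"].to_numpy(), rec_sa,
                                            curv_fits["cgs"].slope)
    rec["normalized_cms"] = normalize_by_sa(rec["cms"].to_numpy(), rec_sa,
                                            curv_fits["cms"].slope)
    rec["region"] = classify_region(rec["normalized_cgs"].to_numpy(),
                                    threshold=cgs_threshold)
    out["records"] = rec

    # 3) scute dimensions vs SA: per region and pooled, plus the
    #    SA × region interaction test
    scute_fits: dict[tuple, object] = {}
    interaction_p = {}
    # the -1000 plane-area flag removes a scute from area analyses only
    rec_ok = rec[rec["area"] != MISSING_FLAG]
    med_all = rec.pivot_table(index="specimen", columns="region",
                              values=SCUTE_DIMENSIONS, aggfunc="median")
    med_area = rec_ok.pivot_table(index="specimen", columns="region",
                                  values=["area"], aggfunc="median")
    med_region = med_all.drop(columns=["area"]).join(med_area)
    for var in SCUTE_DIMENSIONS:
        src = rec_ok if var == "area" else rec
        pooled = src.groupby("specimen")[var].median().loc[ids]
        scute_fits[(var, "both")] = fit_loglog(
            sa.to_numpy(), pooled.to_numpy(), variable=var,
            specimen_ids=ids)
        for region in ("flat", "edge"):
            if (var, region) not in med_region.columns:
                continue
            vals = med_region[(var, region)].loc[ids]
            if vals.isna().any():
                log.warning("variable %s region %s missing for some "
                            "specimens; region fit skipped", var, region)
                continue
            scute_fits[(var, region)] = fit_loglog(
                sa.to_numpy(), vals.to_numpy(), variable=var,
                specimen_ids=ids)
        if ((var, "flat") in scute_fits and (var, "edge") in scute_fits):
            interaction_p[var] = region_interaction_test(
                sa.to_numpy(),
                med_region[(var, "flat")].loc[ids].to_numpy(),
                med_region[(var, "edge")].loc[ids].to_numpy())
    out["scute_fits"] = scute_fits
    out["interaction_p"] = interaction_p

    # 4) shape frequencies (opening scutes excluded)
    out["shape_frequencies"] = shape_frequencies(rec)

    # 5) multivariate analysis on normalized variables
    exponents = {var: scute_fits[(var, "both")].slope
                 for var in SCUTE_DIMENSIONS}
    exponents["cgs"] = curv_fits["cgs"].slope
    exponents["cms"] = curv_fits["cms"].slope
    # Table-1 naming: "width" is the scute's maximum width
    matrix = prepare_matrix(rec, sa_by_specimen, exponents,
                            mad_factor=mad_factor)
    scores, loadings, var_exp = run_pca(matrix)
    model = hierarchical_clusters(scores, k=k_clusters, meta=matrix.meta,
                                  loadings=loadings,
                                  variance_explained=var_exp)
    model = cluster_summaries(model, matrix)
    out["exponents"] = exponents
    out["matrix"] = matrix
    out["pca"] = {"scores": scores, "loadings": loadings,
                  "variance_explained": var_exp}
    out["correlations"] = correlation_panel(matrix)
    out["cluster_model"] = model
    return out


def scaling_table(result: dict) -> pd.DataFrame:
    """Table-1-shaped summary: variable, region, slope, 95% CI."""
    rows = []
    for var, fit in result["dimension_fits"].items():
        rows.append(("carapace_" + var, "", fit.slope, *fit.ci95))
    cf = result["count_fit"]
    rows.append(("scute_number", "", cf.slope, *cf.ci95))
    for var, fit in result["curvature_fits"].items():
        rows.append((var, "both", fit.slope, *fit.ci95))
    for (var, region), fit in result["scute_fits"].items():
        rows.append((var, region, fit.slope, *fit.ci95))
    return pd.DataFrame(rows, columns=["variable", "region", "slope",
                                       "ci_low", "ci_high"])


# ---------------------------------------------------------------------------
# report bundle

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages for ``config`` and write the report bundle.

    Writes specimen summaries, the per-scute table with region labels,
    the Table-1-shaped scaling CSV, residual-by-geometry tables, shape
    frequencies, cluster outputs and a machine-readable manifest.
    Deterministic: rerunning with the same config reproduces every file.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if config.mode == "synthetic":
            specs = simulate_batch(config.seed,
                                   n_specimens=config.n_specimens,
                                   geometry_classes=tuple(
                                       config.geometry_classes),
                                   size_span=config.size_span,
                                   base_length_mm=config.base_length_mm)
            stage = "measure"
            records, summaries, _ = measure_batch(
                specs, min_contact=config.min_contact)
        elif config.mode == "label_volume":
            stage = "measure"
            recs, summs = [], []
            geoms = (config.volume_geometry
                     or [""] * len(config.volume_paths))
            for path, geom in zip(config.volume_paths, geoms):
                vol = btio.read_label_volume(path)
                sid = Path(path).stem
                r, s = measure_specimen(vol, specimen_id=sid,
                                        geometry_class=geom,
                                        min_contact=config.min_contact)
                recs.append(r)
                summs.append(asdict_summary(s))
            records = pd.concat(recs, ignore_index=True)
            summaries = pd.DataFrame(summs)
        else:  # scute_table
            records = btio.read_scute_table(
                config.table_path, column_mapping=config.column_mapping)
            if not config.summaries_path:
                raise ValueError("scute_table mode needs summaries_path "
                                 "with per-specimen SA")
            summaries = pd.read_csv(config.summaries_path)

        stage = "analyze"
        result = analyze_batch(records, summaries,
                               cgs_threshold=config.cgs_threshold,
                               mad_factor=config.mad_factor,
                               k_clusters=config.k_clusters)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}"
                           ) from err

    files = _write_bundle(out_dir, config, result, summaries)
    return {"result": result, "files": files}


def _write_bundle(out_dir: Path, config: RunConfig, result: dict,
                  summaries: pd.DataFrame) -> dict:
    files = {}

    def save(name, df):
        p = out_dir / name
        df.to_csv(p, index=False, float_format="%.10g")
        files[name] = str(p)

    save("specimen_summaries.csv", summaries)
    save("scute_records.csv", result["records"])
    save("scaling_table.csv", scaling_table(result))

    resid_rows = []
    summ_idx = summaries.set_index("specimen")
    for var, fit in {**result["dimension_fits"],
                     "n_scutes": result["count_fit"]}.items():
        classes = [summ_idx.loc[s, "geometry_class"]
                   for s in fit.specimen_ids]
        df = residuals_by_geometry(fit, classes)
        df.insert(0, "variable", var)
        resid_rows.append(df)
    save("residuals_by_geometry.csv", pd.concat(resid_rows,
                                                ignore_index=True))
    save("shape_frequencies.csv", result["shape_frequencies"])
    save("correlations.csv",
         result["correlations"].reset_index(names="variable"))
    save("pc_loadings.csv",
         result["pca"]["loadings"].reset_index(names="variable"))

    model = result["cluster_model"]
    assign = model.meta.copy()
    assign["cluster"] = model.assignment
    save("cluster_assignments.csv", assign)
    save("cluster_summaries.csv", model.summaries)
    save("cluster_frequencies.csv", model.frequencies)
    (out_dir / "linkage_tree.nwk").write_text(
        linkage_to_newick(model.linkage))
    files["linkage_tree.nwk"] = str(out_dir / "linkage_tree.nwk")

    manifest = {"config": asdict(config), "version": __version__,
                "n_scutes_total": int(len(result["records"])),
                "n_retained": int(len(result["matrix"].data)),
                "variance_explained_pc12": float(
                    result["pca"]["variance_explained"][:2].sum())}
    btio.write_json(out_dir / "manifest.json", manifest)
    files["manifest.json"] = str(out_dir / "manifest.json")
    return files


def linkage_to_newick(Z: np.ndarray) -> str:
    """Serialize a scipy linkage matrix as a newick tree string."""
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(Z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"s{node.id}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(root, root.dist) + ";"


# ---------------------------------------------------------------------------
# color-coded mesh export

def export_colored_mesh(surface_or_partition, records: pd.DataFrame,
                        variable: str, path,
                        normalization: dict | None = None,
                        color_range: tuple | None = None,
                        sentinel: float = -1.0) -> int:
    """Write a PLY whose per-face scalar is a scute variable.

    ``surface_or_partition`` is either a CarapaceSurface (faces from
    scute patches) or a SurfacePartition (all faces labeled).  With
    ``normalization = {"sa": ..., "slope": ...}`` values are divided by
    SA^slope first.  Values outside ``color_range`` are clamped and
    counted (the returned value); opening scutes (area −1000) carry the
    sentinel.
    """
    if variable not in records.columns:
        raise KeyError(f"unknown variable {variable!r}")
    vals = {}
    for _, r in records.iterrows():
        v = r[variable]
        if r["area"] == MISSING_FLAG:
            v = None
        elif normalization:
            v = v / normalization["sa"] ** normalization["slope"]
        vals[int(r["scute_id"])] = v

    if hasattr(surface_or_partition, "scute_patch"):
        mesh = surface_or_partition.mesh
        face_scalar = np.full(len(mesh.faces), sentinel, dtype=float)
        owner = {}
        for sid, fl in surface_or_partition.scute_patch.items():
            for f in fl:
                owner[f] = sid
        for f, sid in owner.items():
            v = vals.get(sid)
            face_scalar[f] = sentinel if v is None else v
    else:
        mesh = surface_or_partition.mesh
        labels = surface_or_partition.face_label
        face_scalar = np.array(
            [sentinel if (s == 0 or vals.get(int(s)) is None)
             else vals[int(s)] for s in labels], dtype=float)

    clamped = 0
    if color_range is not None:
        lo, hi = color_range
        real = face_scalar != sentinel
        below = real & (face_scalar < lo)
        above = real & (face_scalar > hi)
        clamped = int(below.sum() + above.sum())
        face_scalar[below] = lo
        face_scalar[above] = hi
        if clamped:
            log.info("%d face values clamped to the color range", clamped)
    btio.write_ply(path, mesh, face_scalar, scalar_name=variable)
    return clamped
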