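"""End-to-end orchestration: files in, artifact bundle out.

``run_pipeline`` executes the seven stages in order — normalise, restrict to
the network, Wasserstein distance matrix, diffusion map, Mapper, state
graph, state calling — writing every intermediate artifact plus a manifest
(parameters, versions, stage wall-times) so a run is reproducible from its
output directory alone.

``scan_parameters`` tabulates Mapper node/edge counts over an (n_f, t) grid
and flags the two degenerate regimes (everything a singleton / everything
one cluster); ``pick_stable`` is a convenience heuristic that returns the
midpoint of the longest stable plateau for scripted runs — interactive
users are expected to inspect the table themselves.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .diffusion import DiffusionMap
from .errors import ValidationError
from .expression import (
    ExpressionMatrix,
    normalize_zscore,
    read_expression,
    restrict_to_network,
    write_expression,
)
from .mapper import FilterValues, Mapper, build_cover, nerve, slice_cluster
from .network import GeneNetwork, read_edge_list, write_graphml
from .stategraph import (
    call_states,
    group_by_paths,
    heatmap_matrices,
    order_samples,
    render_heatmaps,
    states_frame,
)
from .stategraph import write_graphml as write_stategraph_graphml
from .transport import SampleDistanceMatrix, distance_matrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run."""

    expression: str = ""
    network: str = ""
    control: str | None = None
    covariates: str | None = None
    progression: str | None = None  # two-column sample_id<TAB>value filter file
    delimiter: str = "\t"
    mode: str = "density"
    pseudocount: float = 0.0
    epsilon: str | float = "median"
    n_components: int = 2
    selected_indices: tuple[int, ...] | None = None
    filter: str = "centrality"
    n_neighbors: int = 10
    ridge: float = 0.0
    n_intervals: int = 6
    overlap: float = 0.5
    threshold: str | float = "auto"
    min_overlap: int = 1
    delta: float = 1.0 / 6.0
    seed: int = 0
    outdir: str = "wassermap_out"
    render: bool = False

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Read a ``key = value`` text config, then apply overrides."""
        values: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValidationError(f"config line {lineno}: expected key = value")
                key, _, raw = line.partition("=")
                values[key.strip()] = raw.strip()
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_mapping(values)

    @classmethod
    def from_mapping(cls, values: dict) -> "PipelineConfig":
        kwargs: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, raw in values.items():
            if key not in fields:
                raise ValidationError(f"unknown config key {key!r}")
            kwargs[key] = _coerce(key, raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if out["selected_indices"] is not None:
            out["selected_indices"] = list(out["selected_indices"])
        return out


def _coerce(key: str, raw):
    if not isinstance(raw, str):
        return raw
    if key in ("pseudocount", "ridge", "overlap", "delta"):
        return float(raw)
    if key in ("n_components", "n_neighbors", "n_intervals", "min_overlap", "seed"):
        return int(raw)
    if key == "render":
        return raw.lower() in ("1", "true", "yes")
    if key in ("epsilon", "threshold"):
        try:
            return float(raw)
        except ValueError:
            return raw
    if key == "selected_indices":
        raw = raw.strip()
        if not raw or raw.lower() == "none":
            return None
        return tuple(int(p) for p in raw.replace(",", " ").split())
    if key in ("control", "covariates", "progression") and raw.lower() in ("", "none"):
        return None
    return raw


def write_distance_matrix(D: SampleDistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(D.samples) + "\n")
        for sample, row in zip(D.samples, D.D):
            fh.write(sample + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_distance_matrix(path) -> SampleDistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(frame.index) != list(frame.columns):
        raise ValidationError("distance matrix rows and columns disagree")
    return SampleDistanceMatrix(tuple(frame.index), frame.to_numpy(dtype=float))


def write_condensed(D: SampleDistanceMatrix, path) -> None:
    """Upper triangle, row-major, one value per line (pipeable text form)."""
    n = len(D.samples)
    with open(path, "w") as fh:
        for i in range(n):
            for j in range(i + 1, n):
                fh.write(repr(float(D.D[i, j])) + "\n")


def _nerve_components(n_nodes: int, edges) -> int:
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent[find(i)] = find(j)
    return len({find(i) for i in range(n_nodes)})


def scan_parameters(
    points: np.ndarray,
    filter_values: FilterValues | np.ndarray,
    n_f_grid,
    t_grid,
    overlap: float = 0.5,
    min_overlap: int = 1,
    cluster_distances=None,
) -> pd.DataFrame:
    """Mapper complexity over a parameter grid.

    One row per (n_f, t): node/edge/component counts, the largest cluster
    size, and flags for the two extreme regimes ("all_singletons": every
    cluster is one sample; "single_cluster": one cluster holds everything).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    f = filter_values.values if isinstance(filter_values, FilterValues) else np.asarray(filter_values, dtype=float)
    n = points.shape[0]
    rows = []
    for n_f in n_f_grid:
        cover = build_cover(FilterValues(f), int(n_f), overlap)
        membership = cover.membership(f)
        for t in t_grid:
            partitions = []
            for idx in membership:
                if cluster_distances is not None:
                    D = np.asarray(cluster_distances)[np.ix_(idx, idx)]
                    local = slice_cluster(D, float(t), metric="precomputed")
                else:
                    local = slice_cluster(points[idx], float(t))
                partitions.append([idx[c] for c in local])
            complex_ = nerve(partitions, FilterValues(f), min_overlap)
            sizes = [len(node.members) for node in complex_.nodes]
            rows.append(
                {
                    "n_f": int(n_f),
                    "t": float(t),
                    "n_nodes": complex_.n_nodes,
                    "n_edges": complex_.n_edges,
                    "n_components": _nerve_components(complex_.n_nodes, complex_.edges),
                    "max_cluster_size": max(sizes) if sizes else 0,
                    "all_singletons": bool(sizes) and max(sizes) == 1,
                    "single_cluster": bool(sizes) and max(sizes) == n,
                }
            )
    return pd.DataFrame(rows)


def pick_stable(table: pd.DataFrame, prefer: str = "longest") -> tuple[int, float]:
    """Midpoint of a stable plateau of the scan table.

    A plateau is a maximal run of consecutive t values (at fixed n_f) whose
    (node count, edge count) signature is unchanged; rows flagged as extreme
    regimes are excluded.  ``prefer="longest"`` returns the middle of the
    longest plateau — the conventional "stable middle" reading.
    ``prefer="coarsest"`` returns the middle of the largest-t plateau of
    length ≥ 2: branch points of a state graph only resolve once t exceeds
    the arm separation near a junction, so branch-structure analyses should
    read the coarse end of the stable region.
    """
    if prefer not in ("longest", "coarsest"):
        raise ValidationError(f"unknown plateau preference {prefer!r}")
    usable = table[~(table["all_singletons"] | table["single_cluster"])]
    if usable.empty:
        usable = table
    runs: list[pd.DataFrame] = []
    for n_f, group in usable.groupby("n_f"):
        group = group.sort_values("t").reset_index(drop=True)
        start = 0
        for i in range(1, len(group) + 1):
            end_of_run = i == len(group) or (
                (group.loc[i, "n_nodes"], group.loc[i, "n_edges"])
                != (group.loc[i - 1, "n_nodes"], group.loc[i - 1, "n_edges"])
            )
            if end_of_run:
                runs.append(group.iloc[start:i])
                start = i
    if prefer == "longest":
        run = max(runs, key=lambda r: (len(r), -r["n_f"].iloc[0]))
    else:
        stable = [r for r in runs if len(r) >= 2] or runs
        run = max(stable, key=lambda r: r["t"].iloc[-1])
    mid = run.iloc[len(run) // 2]
    return int(mid["n_f"]), float(mid["t"])


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    expression: ExpressionMatrix
    normalized: ExpressionMatrix
    network: GeneNetwork
    distances: SampleDistanceMatrix
    diffusion: DiffusionMap
    mapper: Mapper
    groups: dict
    states: dict
    heatmaps: dict
    artifacts: dict
    sample_ids: list


def _read_progression(path, samples) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t", header=None, names=["sample", "value"])
    lookup = dict(zip(frame["sample"].astype(str), frame["value"].astype(float)))
    missing = [s for s in samples if s not in lookup]
    if missing:
        raise ValidationError(f"progression file lacks samples: {missing[:5]}")
    return np.array([lookup[s] for s in samples])


def _auto_threshold(points, filter_values, n_intervals, overlap, min_overlap,
                    cluster_distances=None, prefer: str = "longest",
                    ) -> tuple[float, pd.DataFrame]:
    from scipy.spatial.distance import pdist

    scale = float(pdist(np.atleast_2d(points)).max())
    if scale == 0:
        raise ValidationError("degenerate embedding: all points coincide")
    t_grid = scale * np.logspace(-3, 0, 25)
    table = scan_parameters(
        points, filter_values, [n_intervals], t_grid, overlap, min_overlap,
        cluster_distances,
    )
    _, t = pick_stable(table, prefer)
    return t, table


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages, writing artifacts and a manifest to ``outdir``."""
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    if isinstance(exc, ValidationError):
                        raise ValidationError(f"stage {name!r}: {exc}") from exc
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Timer()

    def emit(name: str, path: pathlib.Path) -> None:
        artifacts[name] = str(path)

    with stage("load"):
        if not config.expression:
            raise ValidationError("config field 'expression' is required")
        if not config.network:
            raise ValidationError("config field 'network' is required")
        m = read_expression(config.expression, config.delimiter)
        g = read_edge_list(config.network)
        control_m = (
            read_expression(config.control, config.delimiter)
            if config.control
            else None
        )

    with stage("normalize"):
        restricted = restrict_to_network(m, g)
        subnet = g.subnetwork(restricted.genes)
        normalized = normalize_zscore(restricted)
        path = outdir / "restricted.tsv"
        write_expression(restricted, path)
        emit("restricted", path)
        path = outdir / "normalized.tsv"
        write_expression(normalized, path)
        emit("normalized", path)

    with stage("distance"):
        n_study = restricted.n_samples
        if control_m is not None:
            control_r = restrict_to_network(control_m, g)
            combined = ExpressionMatrix(
                pd.concat([restricted.data, control_r.data.loc[restricted.genes]], axis=1)
            )
            D_all = distance_matrix(combined, subnet, config.mode, config.pseudocount)
        else:
            D_all = distance_matrix(restricted, subnet, config.mode, config.pseudocount)
        D = SampleDistanceMatrix(
            D_all.samples[:n_study], D_all.D[:n_study, :n_study]
        )
        path = outdir / "distance_matrix.tsv"
        write_distance_matrix(D, path)
        emit("distance_matrix", path)
        path = outdir / "distance_condensed.txt"
        write_condensed(D, path)
        emit("distance_condensed", path)

    with stage("diffuse"):
        dm = DiffusionMap(
            epsilon=config.epsilon,
            n_components=config.n_components,
            selected_indices=config.selected_indices,
        )
        dm.fit(D_all.D)
        coords_all = dm.embedding_
        coords = coords_all[:n_study]
        samples = list(restricted.samples)
        frame = pd.DataFrame(
            coords,
            index=samples,
            columns=[f"phi_{i}" for i in dm.result_.selected_indices],
        )
        frame.index.name = "sample"
        path = outdir / "embedding.tsv"
        frame.to_csv(path, sep="\t")
        emit("embedding", path)
        eig = pd.DataFrame(
            {"index": np.arange(len(dm.eigenvalues_)), "eigenvalue": dm.eigenvalues_}
        )
        path = outdir / "eigenvalues.tsv"
        eig.to_csv(path, sep="\t", index=False)
        emit("eigenvalues", path)

    with stage("filter"):
        from .mapper import centrality_filter, mahalanobis_filter

        if config.progression:
            fv = FilterValues(_read_progression(config.progression, samples))
        elif config.filter == "mahalanobis":
            if control_m is None:
                raise ValidationError("mahalanobis filter requires a control matrix")
            fv = mahalanobis_filter(coords, coords_all[n_study:], config.ridge)
        elif config.filter == "centrality":
            fv = centrality_filter(coords, config.n_neighbors)
        else:
            raise ValidationError(f"unknown filter {config.filter!r}")
        frame = pd.DataFrame({"sample": samples, "filter": fv.values})
        path = outdir / "filter.tsv"
        frame.to_csv(path, sep="\t", index=False)
        emit("filter", path)

    with stage("mapper"):
        if config.threshold == "auto":
            threshold, table = _auto_threshold(
                coords, fv, config.n_intervals, config.overlap, config.min_overlap
            )
            path = outdir / "scan.tsv"
            table.to_csv(path, sep="\t", index=False)
            emit("scan", path)
        else:
            threshold = float(config.threshold)
        mapper = Mapper(
            filter="user",
            n_intervals=config.n_intervals,
            overlap=config.overlap,
            threshold=threshold,
            min_overlap=config.min_overlap,
        )
        mapper.fit(coords, filter_values=fv)
        path = outdir / "mapper_complex.json"
        path.write_text(mapper.complex_.to_json())
        emit("mapper_complex", path)

    with stage("stategraph"):
        sg = mapper.state_graph_.with_order(mapper.sample_order_)
        path = outdir / "state_graph.json"
        path.write_text(sg.to_json())
        emit("state_graph", path)
        path = outdir / "state_graph.graphml"
        write_stategraph_graphml(sg, path)
        emit("state_graph_graphml", path)
        order_ids = [samples[i] for i in mapper.sample_order_]
        path = outdir / "sample_order.txt"
        path.write_text("\n".join(order_ids) + "\n")
        emit("sample_order", path)

    with stage("states"):
        groups = group_by_paths(sg, samples)
        states = call_states(normalized, groups, config.delta)
        frame = states_frame(states)
        path = outdir / "state_calls.tsv"
        frame.to_csv(path, sep="\t", index=False)
        emit("state_calls", path)

    with stage("heatmaps"):
        covariates = (
            pd.read_csv(config.covariates, sep="\t", index_col=0, dtype=str)
            if config.covariates
            else None
        )
        heatmaps = heatmap_matrices(normalized, sg, D, coords, fv, covariates)
        for name, frame in heatmaps.items():
            path = outdir / f"heatmap_{name}.tsv"
            frame.to_csv(path, sep="\t")
            emit(f"heatmap_{name}", path)
        if config.render:
            for png in render_heatmaps(heatmaps, outdir):
                emit(pathlib.Path(png).stem, pathlib.Path(png))

    with stage("manifest"):
        import networkx
        import scipy
        import sklearn

        resolved = config.to_dict()
        resolved["threshold_resolved"] = threshold
        manifest = {
            "parameters": resolved,
            "versions": {
                "wassermap": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "networkx": networkx.__version__,
                "scikit-learn": sklearn.__version__,
            },
            "stage_seconds": timings,
            "artifacts": sorted(artifacts),
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=1, default=str))
        emit("manifest", path)

    return PipelineResult(
        config=config,
        expression=m,
        normalized=normalized,
        network=subnet,
        distances=D,
        diffusion=dm,
        mapper=mapper,
        groups=groups,
        states=states,
        heatmaps=heatmaps,
        artifacts=artifacts,
        sample_ids=samples,
    )
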