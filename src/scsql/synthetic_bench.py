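"""Synthetic cell-by-gene fixtures, the six-query comparison suite, and the
paired runtime-comparison harness.

The generator emulates the simulated datasets used for runtime profiling:
fully dense random expression matrices (1,000 up to 250,000 cells; 10,000
genes by default) with an obs layer of random cell-type assignments, seeded
and bit-reproducible, writable to H5AD.

The query suite runs six queries of increasing complexity against either a
database handle (SQL path) or the in-memory bundle (dense-scan path).
Benchmarking is correctness-gated: before any timing is reported, the timed
path's result must equal the dense oracle value-for-value; a mismatch is a
hard failure. Method comparisons use a paired t-test per library size with
Bonferroni correction across sizes.
"""
from __future__ import annotations

import hashlib
import math
import time
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .database_io import DatabaseHandle, reconstruct_bundle
from .errors import BenchmarkIntegrityError, PairingError
from .query_engine import query

DEFAULT_N_GENES = 10_000
DEFAULT_REPLICATES = 6
#: default desk-scale library-size ladder; the profiled sizes extend to 250k
DEFAULT_SIZES = (1_000, 5_000, 10_000, 25_000, 50_000)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``uniform`` draws expression on [0, 10); ``negative-binomial`` draws
    counts with the given mean and dispersion (variance = mean +
    dispersion * mean^2) for more count-like data. Identical specs (seed
    included) produce bit-identical datasets.
    """

    n_cells: int
    n_genes: int = DEFAULT_N_GENES
    n_cell_types: int = 5
    value_distribution: str = "uniform"
    seed: int = 0
    nb_mean: float = 2.0
    nb_dispersion: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be >= 1")
        if self.value_distribution not in ("uniform", "negative-binomial"):
            raise ValueError(
                "value_distribution must be 'uniform' or 'negative-binomial'"
            )
        if self.n_cell_types < 1:
            raise ValueError("n_cell_types must be >= 1")


def generate_dataset(spec: SyntheticSpec, h5ad_path=None):
    """Generate a dense random expression bundle per ``spec``; optionally
    write it to an H5AD file ready for backed-mode ingestion."""
    import anndata

    rng = np.random.default_rng(spec.seed)
    if spec.value_distribution == "uniform":
        X = rng.random((spec.n_cells, spec.n_genes), dtype=np.float32) * 10.0
    else:
        r = 1.0 / spec.nb_dispersion
        p = r / (r + spec.nb_mean)
        X = rng.negative_binomial(r, p, size=(spec.n_cells, spec.n_genes)).astype(
            np.float32
        )
    obs = pd.DataFrame(
        {
            "cell_type": [
                f"T{t}" for t in rng.integers(0, spec.n_cell_types, spec.n_cells)
            ]
        },
        index=[f"cell_{i}" for i in range(spec.n_cells)],
    )
    bundle = anndata.AnnData(X=X, obs=obs)
    bundle.var_names = [f"gene_{j}" for j in range(spec.n_genes)]
    if h5ad_path is not None:
        bundle.write_h5ad(h5ad_path)
    return bundle


def dataset_digest(bundle) -> str:
    """Content digest of a bundle (X bytes, cell ids, labels, gene names);
    equal specs yield equal digests."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(bundle.X).tobytes())
    h.update("\x00".join(map(str, bundle.obs_names)).encode())
    h.update("\x00".join(map(str, bundle.var_names)).encode())
    for col in bundle.obs.columns:
        h.update("\x00".join(map(str, bundle.obs[col])).encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# query suite
# ---------------------------------------------------------------------------


@dataclass
class BenchQuery:
    """One benchmark query: the SQL text for the database path and an
    equivalent dense evaluation over the in-memory bundle (the oracle)."""

    query_id: int
    description: str
    sql: str
    dense: Callable[[object], pd.DataFrame]


@dataclass
class BenchResult:
    """One timed replicate of one query for one method at one library size."""

    method_label: str
    library_size: int
    query_id: int
    replicate: int
    wall_time: float


def default_query_suite(
    var_names: Sequence[str], threshold: float = 5.0, low: float = 2.0
) -> list[BenchQuery]:
    """The default six-query suite of increasing complexity.

    (1) single-gene select, (2) single-gene threshold filter, (3) two-gene
    conjunctive filter, (4) per-gene AVG over all cells, (5) group-by
    cell-type aggregate, (6) obs-joined filtered aggregate. Fully
    replaceable: pass any list of :class:`BenchQuery` to the runner.
    """
    g0, g1, g2 = var_names[0], var_names[1 % len(var_names)], var_names[2 % len(var_names)]
    all_genes = list(map(str, var_names))

    def col(bundle, gene):
        return np.asarray(bundle[:, gene].X).ravel().astype(np.float64)

    def cells(bundle):
        return np.asarray(bundle.obs_names, dtype=object)

    def q1(bundle):
        df = pd.DataFrame({"cell_id": cells(bundle), str(g0): col(bundle, g0)})
        return df.sort_values("cell_id", ignore_index=True)

    def q2(bundle):
        mask = col(bundle, g0) > threshold
        df = pd.DataFrame(
            {"cell_id": cells(bundle)[mask], str(g0): col(bundle, g0)[mask]}
        )
        return df.sort_values("cell_id", ignore_index=True)

    def q3(bundle):
        mask = (col(bundle, g1) > threshold) & (col(bundle, g2) <= low)
        return pd.DataFrame({"cell_id": cells(bundle)[mask]}).sort_values(
            "cell_id", ignore_index=True
        )

    def q4(bundle):
        means = np.asarray(bundle.X, dtype=np.float64).mean(axis=0)
        return pd.DataFrame([means], columns=all_genes)

    def q5(bundle):
        df = pd.DataFrame(
            {"cell_type": bundle.obs["cell_type"].astype(str), "v": col(bundle, g0)}
        )
        out = df.groupby("cell_type", observed=True)["v"].mean().reset_index()
        out.columns = ["cell_type", "avg_expr"]
        return out.sort_values("cell_type", ignore_index=True)

    def q6(bundle):
        mask = col(bundle, g1) > threshold
        df = pd.DataFrame(
            {
                "cell_type": bundle.obs["cell_type"].astype(str)[mask].to_numpy(),
                "v": col(bundle, g0)[mask],
            }
        )
        out = (
            df.groupby("cell_type", observed=True)["v"]
            .agg(["size", "mean"])
            .reset_index()
        )
        out.columns = ["cell_type", "n_cells", "avg_expr"]
        out["n_cells"] = out["n_cells"].astype(np.int64)
        return out.sort_values("cell_type", ignore_index=True)

    qi = lambda g: f'"{g}"'
    avg_cols = ", ".join(f'AVG({qi(g)}) AS {qi(g)}' for g in all_genes)
    return [
        BenchQuery(
            1,
            "single-gene select",
            f'SELECT cell_id, {qi(g0)} FROM X ORDER BY cell_id',
            q1,
        ),
        BenchQuery(
            2,
            "single-gene threshold filter",
            f'SELECT cell_id, {qi(g0)} FROM X WHERE {qi(g0)} > {threshold} '
            "ORDER BY cell_id",
            q2,
        ),
        BenchQuery(
            3,
            "two-gene conjunctive filter",
            f'SELECT cell_id FROM X WHERE {qi(g1)} > {threshold} AND {qi(g2)} <= {low} '
            "ORDER BY cell_id",
            q3,
        ),
        BenchQuery(4, "per-gene average over all cells", f"SELECT {avg_cols} FROM X", q4),
        BenchQuery(
            5,
            "group-by cell-type aggregate",
            'SELECT cell_type, AVG({g}) AS avg_expr FROM adata GROUP BY cell_type '
            "ORDER BY cell_type".format(g=qi(g0)),
            q5,
        ),
        BenchQuery(
            6,
            "obs-joined filtered aggregate",
            'SELECT cell_type, COUNT(*) AS n_cells, AVG({g0}) AS avg_expr FROM adata '
            "WHERE {g1} > {t} GROUP BY cell_type ORDER BY cell_type".format(
                g0=qi(g0), g1=qi(g1), t=threshold
            ),
            q6,
        ),
    ]


def _results_match(db_frame: pd.DataFrame, oracle_frame: pd.DataFrame) -> bool:
    if db_frame.shape != oracle_frame.shape:
        return False
    if list(db_frame.columns) != list(oracle_frame.columns):
        return False
    for col in db_frame.columns:
        a, b = db_frame[col], oracle_frame[col]
        if pd.api.types.is_numeric_dtype(b):
            # X values are stored at FLOAT (single) precision
            if not np.allclose(
                a.to_numpy(dtype=np.float64),
                b.to_numpy(dtype=np.float64),
                rtol=1e-5,
                atol=1e-5,
            ):
                return False
        elif not (a.astype(str).to_numpy() == b.astype(str).to_numpy()).all():
            return False
    return True


def run_query_suite(
    target,
    suite: Sequence[BenchQuery] | None = None,
    replicates: int = DEFAULT_REPLICATES,
    method_label: str | None = None,
    oracle_bundle=None,
) -> tuple[dict[int, pd.DataFrame], list[BenchResult]]:
    """Run the suite on a database handle (SQL path) or a bundle (dense-scan
    path), returning per-query results and timed replicates.

    Every query's result is checked against the dense oracle *before* any
    timing is recorded; a mismatch raises :class:`BenchmarkIntegrityError`
    and no timings exist for that query. For a database target the oracle
    bundle defaults to the database's own reconstructed contents.
    """
    is_db = isinstance(target, DatabaseHandle)
    if is_db and oracle_bundle is None:
        oracle_bundle = reconstruct_bundle(target)
    if not is_db and oracle_bundle is None:
        oracle_bundle = target
    if suite is None:
        suite = default_query_suite(list(map(str, oracle_bundle.var_names)))
    if method_label is None:
        method_label = "database" if is_db else "dense-scan"
    library_size = oracle_bundle.n_obs

    results: dict[int, pd.DataFrame] = {}
    timings: list[BenchResult] = []
    for bench_query in suite:
        def run_once():
            if is_db:
                return query(target, bench_query.sql)
            return bench_query.dense(target)

        produced = run_once()
        oracle = bench_query.dense(oracle_bundle)
        if not _results_match(produced, oracle):
            raise BenchmarkIntegrityError(
                f"query {bench_query.query_id} ({bench_query.description}) on "
                f"method {method_label!r} disagrees with the dense oracle; "
                "refusing to report timings for a wrong answer"
            )
        results[bench_query.query_id] = produced
        for replicate in range(1, replicates + 1):
            start = time.perf_counter()
            run_once()
            timings.append(
                BenchResult(
                    method_label,
                    library_size,
                    bench_query.query_id,
                    replicate,
                    time.perf_counter() - start,
                )
            )
    return results, timings


# ---------------------------------------------------------------------------
# paired comparison statistics
# ---------------------------------------------------------------------------


def paired_t_pvalue(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided paired t-test; returns (t, p, degenerate).

    Zero variance of the differences is degenerate: all-equal pairs give
    (0, 1); a constant nonzero shift gives (signed inf, 0) and is flagged.
    """
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    n = d.size
    if n < 2:
        raise PairingError("paired t-test requires at least 2 pairs")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0, True
        return math.copysign(math.inf, mean), 0.0, True
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p), False


def _to_frame(results: Sequence[BenchResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.method_label, r.library_size, r.query_id, r.replicate, r.wall_time)
            for r in results
        ],
        columns=["method_label", "library_size", "query_id", "replicate", "wall_time"],
    )


def compare_methods(
    results_a: Sequence[BenchResult],
    results_b: Sequence[BenchResult],
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Per-library-size paired t-test between two methods' matched timings,
    Bonferroni-corrected across the number of sizes tested.

    Replicates are paired on (library_size, query_id, replicate); an
    unmatched design raises :class:`PairingError`. The significance flag is
    ``p_bonferroni < alpha`` (default .001).
    """
    fa, fb = _to_frame(results_a), _to_frame(results_b)
    key = ["library_size", "query_id", "replicate"]
    fa = fa.sort_values(key, ignore_index=True)
    fb = fb.sort_values(key, ignore_index=True)
    if len(fa) != len(fb) or not (fa[key].to_numpy() == fb[key].to_numpy()).all():
        raise PairingError(
            "methods do not share a matched (library_size, query_id, replicate) design"
        )
    sizes = sorted(fa["library_size"].unique())
    n_sizes = len(sizes)
    rows = []
    for size in sizes:
        mask = fa["library_size"] == size
        t, p, degenerate = paired_t_pvalue(
            fa.loc[mask, "wall_time"].to_numpy(), fb.loc[mask, "wall_time"].to_numpy()
        )
        p_bonf = min(p * n_sizes, 1.0)
        rows.append(
            {
                "library_size": size,
                "n_pairs": int(mask.sum()),
                "t_statistic": t,
                "p_value": p,
                "p_bonferroni": p_bonf,
                "significant": bool(p_bonf < alpha),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scaling comparison
# ---------------------------------------------------------------------------


def scaling_benchmark(
    sizes: Sequence[int] = (25_000, 50_000),
    n_genes: int = 500,
    seed: int = 0,
    replicates: int = 3,
    chunk_size: int = 5_000,
) -> pd.DataFrame:
    """Total suite wall time (best-of-replicates per query, summed) for the
    database path vs the dense-scan path at each library size."""
    from .database_io import make_db

    rows = []
    for size in sizes:
        bundle = generate_dataset(
            SyntheticSpec(n_cells=size, n_genes=n_genes, seed=seed)
        )
        db = make_db(bundle, chunk_size=chunk_size)
        suite = default_query_suite(list(map(str, bundle.var_names)))
        try:
            _, db_times = run_query_suite(
                db, suite, replicates=replicates, oracle_bundle=bundle
            )
        finally:
            db.close()
        _, dense_times = run_query_suite(bundle, suite, replicates=replicates)
        for label, timings in (("database", db_times), ("dense-scan", dense_times)):
            per_query = _to_frame(timings).groupby("query_id")["wall_time"].min()
            rows.append(
                {
                    "method_label": label,
                    "library_size": size,
                    "suite_time": float(per_query.sum()),
                }
            )
    return pd.DataFrame(rows)


def scaling_growth_factors(scaling: pd.DataFrame) -> dict[str, float]:
    """Growth factor of total suite time from the smallest to the largest
    library size, per method."""
    out = {}
    for label, group in scaling.groupby("method_label"):
        group = group.sort_values("library_size")
        out[str(label)] = float(
            group["suite_time"].iloc[-1] / group["suite_time"].iloc[0]
        )
    return out
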