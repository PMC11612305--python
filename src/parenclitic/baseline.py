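"""The non-aggressive baseline: one bivariate mixture per locus pair.

The baseline describes the joint beta-value distribution of every unordered
pair of panel loci in the reference (non-aggressive, "modeling") cohort. A
new sample's deviation at a pair is the Mahalanobis distance from its
observed ``(beta_i, beta_j)`` point to the *closest* mixture component,

    w(cg_i, cg_j) = min_n d_M((beta_i, beta_j), mu_n; Sigma_n),

using each candidate component's own covariance. These weights are the
edges of the sample's parenclitic network.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .exceptions import ParseError, ValidationError
from .gmm import GMMSettings, PairGMM, fit_gmm_batch
from .io_qc import BetaMatrix
from .panel import LocusPanel
from .utils import pair_uniforms

log = logging.getLogger(__name__)

__all__ = ["BaselineModel", "fit_baseline", "mahalanobis_to_component", "edge_weight"]

_MAGIC = b"PARENCLITIC-BASELINE-1\n"


def mahalanobis_to_component(point, mean, covariance) -> float:
    """sqrt((x - mu)^T Sigma^-1 (x - mu)) via a Cholesky solve.

    Raises ValidationError if the covariance is not symmetric positive
    definite.
    """
    x = np.asarray(point, dtype=np.float64)
    mu = np.asarray(mean, dtype=np.float64)
    cov = np.asarray(covariance, dtype=np.float64)
    if not np.allclose(cov, cov.T):
        raise ValidationError("covariance matrix is not symmetric")
    try:
        factor = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("covariance matrix is not positive definite") from exc
    diff = x - mu
    return float(np.sqrt(diff @ cho_solve(factor, diff)))


def edge_weight(point, model: PairGMM) -> float:
    """Minimum Mahalanobis distance from the point to any mixture component."""
    return min(
        mahalanobis_to_component(point, model.means[k], model.covariances[k])
        for k in range(model.n_components)
    )


@dataclass
class BaselineModel:
    """Per-pair mixtures for all C(k, 2) pairs of the locus panel.

    Component arrays are padded to ``max_components`` along axis 1; entries
    beyond ``n_components[p]`` are NaN (means/covariances) or 0 (weights).
    Pairs are stored in upper-triangle order, matching
    ``numpy.triu_indices(k, 1)``.
    """

    panel: LocusPanel
    n_components: np.ndarray      # (P,)
    weights: np.ndarray           # (P, kmax)
    means: np.ndarray             # (P, kmax, 2)
    covariances: np.ndarray       # (P, kmax, 2, 2)
    bic: np.ndarray               # (P, kmax)
    master_seed: int
    settings: GMMSettings = field(default_factory=GMMSettings)
    _inv: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        k = len(self.panel)
        expected = k * (k - 1) // 2
        if self.n_components.shape[0] != expected:
            raise ValidationError(
                f"expected {expected} pair models for a {k}-locus panel, "
                f"got {self.n_components.shape[0]}")
        self._iu, self._ju = np.triu_indices(k, 1)
        self._index = {locus: i for i, locus in enumerate(self.panel.loci)}

    # ------------------------------------------------------------------ pairs
    @property
    def n_pairs(self) -> int:
        return self.n_components.shape[0]

    def pair_position(self, i: int, j: int) -> int:
        """Condensed index of panel pair (i, j), i != j."""
        k = len(self.panel)
        if i == j:
            raise ValidationError("a pair requires two distinct loci")
        if i > j:
            i, j = j, i
        return (2 * k - i - 1) * i // 2 + (j - i - 1)

    def get_pair(self, locus_a: str, locus_b: str) -> PairGMM:
        """The fitted mixture for a pair of loci, in canonical (i < j) order."""
        try:
            i, j = self._index[locus_a], self._index[locus_b]
        except KeyError as exc:
            raise ValidationError(f"locus {exc.args[0]!r} is not in the panel") from exc
        p = self.pair_position(i, j)
        k = int(self.n_components[p])
        return PairGMM(
            pair=(min(i, j), max(i, j)),
            weights=self.weights[p, :k].copy(),
            means=self.means[p, :k].copy(),
            covariances=self.covariances[p, :k].copy(),
            bic={kk + 1: float(b) for kk, b in enumerate(self.bic[p])},
            converged={},
        )

    # ----------------------------------------------------------- edge weights
    def _inverse_covariances(self) -> np.ndarray:
        if self._inv is None:
            covs = self.covariances.copy()
            invalid = ~np.isfinite(covs).all(axis=(2, 3))
            covs[invalid] = np.eye(2)
            self._inv = np.linalg.inv(covs)
        return self._inv

    def edge_weights(self, sample_betas: np.ndarray) -> np.ndarray:
        """All C(k, 2) edge weights for one sample's panel beta vector."""
        b = np.asarray(sample_betas, dtype=np.float64)
        if b.shape != (len(self.panel),):
            raise ValidationError(
                f"expected {len(self.panel)} beta values, got shape {b.shape}")
        x = np.stack((b[self._iu], b[self._ju]), axis=-1)     # (P, 2)
        diff = x[:, None, :] - self.means                     # (P, kmax, 2)
        inv = self._inverse_covariances()
        valid = np.arange(self.means.shape[1])[None, :] < self.n_components[:, None]
        diff = np.where(valid[..., None], diff, 0.0)
        d2 = np.einsum("pkd,pkde,pke->pk", diff, inv, diff)
        d2 = np.where(valid, d2, np.inf)
        return np.sqrt(d2.min(axis=1))

    # ---------------------------------------------------------- serialization
    def save(self, path) -> None:
        """Write a deterministic archive: JSON header + raw array bytes."""
        arrays = {
            "n_components": self.n_components.astype(np.int64),
            "weights": self.weights.astype(np.float64),
            "means": self.means.astype(np.float64),
            "covariances": self.covariances.astype(np.float64),
            "bic": self.bic.astype(np.float64),
        }
        header = {
            "schema": 1,
            "panel": list(self.panel.loci),
            "panel_provenance": {k: str(v) for k, v in sorted(self.panel.provenance.items())},
            "master_seed": self.master_seed,
            "settings": {
                "max_components": self.settings.max_components,
                "n_init": self.settings.n_init,
                "covariance_floor": self.settings.covariance_floor,
                "tol": self.settings.tol,
                "max_iter": self.settings.max_iter,
                "chunk_size": self.settings.chunk_size,
            },
            "arrays": {name: {"dtype": str(a.dtype), "shape": list(a.shape)}
                       for name, a in arrays.items()},
        }
        blob = json.dumps(header, sort_keys=True).encode()
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(len(blob).to_bytes(8, "little"))
            fh.write(blob)
            for name in sorted(arrays):
                fh.write(np.ascontiguousarray(arrays[name]).tobytes())

    @classmethod
    def load(cls, path) -> "BaselineModel":
        with open(path, "rb") as fh:
            magic = fh.read(len(_MAGIC))
            if magic != _MAGIC:
                raise ParseError(f"{path} is not a baseline archive")
            size = int.from_bytes(fh.read(8), "little")
            header = json.loads(fh.read(size).decode())
            arrays = {}
            for name in sorted(header["arrays"]):
                spec = header["arrays"][name]
                dtype = np.dtype(spec["dtype"])
                shape = tuple(spec["shape"])
                count = int(np.prod(shape)) if shape else 1
                data = fh.read(count * dtype.itemsize)
                arrays[name] = np.frombuffer(data, dtype=dtype).reshape(shape).copy()
        s = header["settings"]
        return cls(
            panel=LocusPanel(loci=tuple(header["panel"]),
                             provenance=dict(header.get("panel_provenance", {}))),
            n_components=arrays["n_components"],
            weights=arrays["weights"],
            means=arrays["means"],
            covariances=arrays["covariances"],
            bic=arrays["bic"],
            master_seed=int(header["master_seed"]),
            settings=GMMSettings(**s),
        )


def fit_baseline(beta_modeling: BetaMatrix, panel: LocusPanel,
                 settings: GMMSettings | None = None,
                 master_seed: int = 0) -> BaselineModel:
    """Fit a mixture for every unordered pair of panel loci.

    ``beta_modeling`` must contain only the reference-cohort samples. Each
    pair's fit is seeded from ``(master_seed, i, j)`` so the result does not
    depend on chunking or execution order. Progress is logged per chunk.
    """
    settings = settings or GMMSettings()
    missing = [p for p in panel.loci if p not in set(beta_modeling.probe_ids)]
    if missing:
        raise ValidationError(f"panel loci absent from beta matrix: {missing[:10]}")
    V = beta_modeling.frame.loc[list(panel.loci)].to_numpy()
    nan_rows = np.isnan(V).any(axis=1)
    if nan_rows.any():
        bad = [panel.loci[i] for i in np.where(nan_rows)[0]]
        raise ValidationError(f"missing beta values at panel loci: {bad[:10]}")
    k = len(panel)
    iu, ju = np.triu_indices(k, 1)
    P = iu.size
    kmax = min(settings.max_components, V.shape[1])

    n_components = np.empty(P, dtype=np.int64)
    weights = np.zeros((P, kmax))
    means = np.full((P, kmax, 2), np.nan)
    covariances = np.full((P, kmax, 2, 2), np.nan)
    bic = np.full((P, kmax), np.nan)

    n_draws = settings.n_uniforms()
    chunk = max(1, settings.chunk_size)
    for start in range(0, P, chunk):
        sl = slice(start, min(start + chunk, P))
        X = np.stack((V[iu[sl]], V[ju[sl]]), axis=-1)
        u = pair_uniforms(master_seed, iu[sl], ju[sl], n_draws)
        res = fit_gmm_batch(X, u, settings)
        n_components[sl] = res.n_components
        weights[sl] = res.weights
        means[sl] = res.means
        covariances[sl] = res.covariances
        bic[sl] = res.bic
        log.info("baseline fit: %d / %d pairs done", sl.stop, P)

    return BaselineModel(
        panel=panel,
        n_components=n_components,
        weights=weights,
        means=means,
        covariances=covariances,
        bic=bic,
        master_seed=master_seed,
        settings=settings,
    )
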