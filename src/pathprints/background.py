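"""Platform backgrounds: uniform-normal mixtures and signed POE.

For every pathway, the distribution of mean-squared-rank scores across a
large, heterogeneous set of arrays from one platform is fitted with a
two-component mixture,

    y ~ pi * U(lo, hi) + (1 - pi) * N(mu, sigma^2),

where the normal component models the core of typical pathway expression and
the uniform component models outlying (significantly high or low) scores.
The fit is by EM with the uniform support held fixed at the observed range
(a free-support uniform makes the likelihood ill-posed), so the procedure is
deterministic and needs no seed.

A new sample's score y is then normalized to a signed probability of
expression (POE): the posterior probability that y belongs to the uniform
component, signed by which side of the normal mean it falls on,

    POE(y) = sign(y - mu) * pi*f_U(y) / (pi*f_U(y) + (1-pi)*f_N(y)).

When scoring new samples the uniform density is evaluated as the constant
1/(hi-lo) everywhere, so scores beyond the background's observed range get
|POE| -> 1 rather than an undefined density.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genesets import GeneSetCollection, collection_id
from .scoring import PathwayScoreMatrix

__all__ = [
    "EMConfig",
    "MixtureFit",
    "PlatformBackground",
    "fit_uniform_normal_em",
    "build_background",
    "poe_transform",
    "save_background",
    "load_background",
]


@dataclass(frozen=True)
class EMConfig:
    """EM settings for the uniform-normal fit.

    n_min        minimum background observations per pathway
    tol          stop when the log-likelihood improves by less than this
    max_iter     iteration cap
    pi0          initial outlier-component weight
    support_eps  uniform support padding, as a fraction of the observed range
    sigma_floor  lower bound on sigma, as a fraction of the support width
    """

    n_min: int = 50
    tol: float = 1e-8
    max_iter: int = 1000
    pi0: float = 0.1
    support_eps: float = 1e-3
    sigma_floor: float = 1e-6


@dataclass
class MixtureFit:
    """Fitted two-component uniform-normal mixture for one pathway."""

    pi_uniform: float
    mu: float
    sigma: float
    lo: float
    hi: float
    loglik: float
    n_obs: int
    converged: bool
    iterations: int
    loglik_path: list[float] = field(default_factory=list)

    def poe(self, y: np.ndarray | float) -> np.ndarray | float:
        """Signed probability of expression for score(s) y under this fit."""
        y = np.asarray(y, dtype=float)
        f_u = 1.0 / (self.hi - self.lo)
        f_n = norm.pdf(y, loc=self.mu, scale=self.sigma)
        num = self.pi_uniform * f_u
        p = num / (num + (1.0 - self.pi_uniform) * f_n)
        # keep strictly inside (-1, 1) even when f_n underflows in the far tail
        p = np.minimum(p, np.nextafter(1.0, 0.0))
        signed = p * np.sign(y - self.mu)
        return signed if signed.ndim else float(signed)


def _loglik(y: np.ndarray, pi: float, mu: float, sigma: float, f_u: float) -> float:
    dens = pi * f_u + (1.0 - pi) * norm.pdf(y, loc=mu, scale=sigma)
    return float(np.log(dens).sum())


def fit_uniform_normal_em(
    values: np.ndarray | pd.Series,
    config: EMConfig = EMConfig(),
    label: str = "",
) -> MixtureFit:
    """Fit y ~ pi*U(lo,hi) + (1-pi)*N(mu,sigma^2) by EM.

    The uniform support is fixed at [min - eps, max + eps]; pi, mu, sigma are
    updated until the log-likelihood improvement drops below ``config.tol``.
    Initialization is pi0 / median / 1.4826*MAD, so the fit is deterministic.
    """
    y = np.asarray(values, dtype=float)
    y = y[np.isfinite(y)]
    tag = f" for {label!r}" if label else ""
    if y.size < config.n_min:
        raise ValueError(f"need at least {config.n_min} observations{tag}, got {y.size}")
    rng_width = float(np.ptp(y))
    if rng_width == 0.0:
        raise ValueError(f"background scores{tag} are constant; cannot fit a mixture")

    eps = config.support_eps * rng_width
    lo, hi = float(y.min() - eps), float(y.max() + eps)
    f_u = 1.0 / (hi - lo)
    sigma_floor = config.sigma_floor * (hi - lo)

    pi = config.pi0
    mu = float(np.median(y))
    sigma = max(1.4826 * float(np.median(np.abs(y - mu))), sigma_floor)

    path = [_loglik(y, pi, mu, sigma, f_u)]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        # E-step: responsibility of the uniform component
        f_n = norm.pdf(y, loc=mu, scale=sigma)
        num = pi * f_u
        r = num / (num + (1.0 - pi) * f_n)
        # M-step
        pi = float(np.clip(r.mean(), 0.0, 1.0))
        w = 1.0 - r
        w_sum = w.sum()
        if w_sum > 0:
            mu = float((w * y).sum() / w_sum)
            sigma = max(math.sqrt(float((w * (y - mu) ** 2).sum() / w_sum)), sigma_floor)
        ll = _loglik(y, pi, mu, sigma, f_u)
        path.append(ll)
        if ll - path[-2] < config.tol:
            converged = True
            break

    return MixtureFit(
        pi_uniform=pi,
        mu=mu,
        sigma=sigma,
        lo=lo,
        hi=hi,
        loglik=path[-1],
        n_obs=int(y.size),
        converged=converged,
        iterations=it,
        loglik_path=path,
    )


@dataclass
class PlatformBackground:
    """Per-pathway mixture fits defining the POE null for one platform.

    ``fits`` maps pathway name -> MixtureFit, or a string reason when no fit
    exists ("unscored", "insufficient_data", "constant"). ``collection_hash``
    pins the exact gene-set collection the background was built against.
    """

    platform: str
    collection_hash: str
    fits: dict[str, MixtureFit | str]
    created: str = ""  # optional provenance; empty keeps outputs byte-stable
    tool_version: str = ""

    def fit_for(self, pathway: str) -> MixtureFit | None:
        f = self.fits.get(pathway)
        return f if isinstance(f, MixtureFit) else None


def build_background(
    score_matrix: PathwayScoreMatrix,
    col: GeneSetCollection,
    config: EMConfig = EMConfig(),
) -> PlatformBackground:
    """Fit one uniform-normal mixture per pathway from a background score matrix."""
    if score_matrix.collection_hash != collection_id(col):
        raise ValueError("score matrix was not computed against this collection")
    fits: dict[str, MixtureFit | str] = {}
    for name in col.names:
        if name not in score_matrix.scores.index:
            fits[name] = "unscored"
            continue
        vals = score_matrix.scores.loc[name].dropna().to_numpy()
        if vals.size < config.n_min:
            fits[name] = "insufficient_data"
        elif np.ptp(vals) == 0:
            fits[name] = "constant"
        else:
            fits[name] = fit_uniform_normal_em(vals, config, label=name)
    return PlatformBackground(
        platform=score_matrix.platform,
        collection_hash=score_matrix.collection_hash,
        fits=fits,
    )


def poe_transform(scores: PathwayScoreMatrix, bg: PlatformBackground) -> pd.DataFrame:
    """Convert a pathway score matrix to signed POE against a fitted background.

    Returns a pathways-by-samples frame in (-1, 1); NaN where the score or
    the background fit is absent. Refuses mismatched collections/platforms:
    silent misalignment of fingerprint coordinates is the worst failure mode.
    """
    if scores.collection_hash != bg.collection_hash:
        raise ValueError(
            "collection mismatch: scores were computed against a different "
            "gene-set collection than this background"
        )
    if bg.platform and scores.platform and bg.platform != scores.platform:
        raise ValueError(f"platform mismatch: {scores.platform!r} vs {bg.platform!r}")
    out = pd.DataFrame(
        np.nan, index=scores.scores.index, columns=scores.scores.columns
    )
    for name in scores.scores.index:
        fit = bg.fit_for(name)
        if fit is None:
            continue
        row = scores.scores.loc[name].to_numpy()
        mask = np.isfinite(row)
        vals = np.full(row.shape, np.nan)
        if mask.any():
            vals[mask] = fit.poe(row[mask])
        out.loc[name] = vals
    return out


# --- persistence -----------------------------------------------------------

def save_background(bg: PlatformBackground, path: str | Path) -> None:
    """Persist a background as self-describing JSON (atomic write)."""
    doc = {
        "format": "pathprints-background/1",
        "platform": bg.platform,
        "collection_hash": bg.collection_hash,
        "created": bg.created,
        "tool_version": bg.tool_version,
        "fits": {
            name: (asdict(f) if isinstance(f, MixtureFit) else {"absent": f})
            for name, f in bg.fits.items()
        },
    }
    tmp = str(path) + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)


def load_background(path: str | Path) -> PlatformBackground:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "pathprints-background/1":
        raise ValueError(f"{path}: not a pathprints background file")
    fits: dict[str, MixtureFit | str] = {}
    for name, f in doc["fits"].items():
        fits[name] = f["absent"] if "absent" in f else MixtureFit(**f)
    return PlatformBackground(
        platform=doc["platform"],
        collection_hash=doc["collection_hash"],
        fits=fits,
        created=doc.get("created", ""),
        tool_version=doc.get("tool_version", ""),
    )
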