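"""Composite-observation bookkeeping, twin-fraction estimation,
detwinning and Laue -1 merging.

A non-merohedral twin yields three kinds of measured intensities:
singles of domain 1, singles of domain 2, and composites in which the
spots of several domains overlap, I_obs ~ sum_k f_k I_k.  The exchange
format for such data is the SHELX HKLF5 fixed-width file, where a
negative batch number marks a component that belongs to the group
closed by the next positive-batch record.

Twin fractions are estimated scale-invariantly: the model
I_i = s * sum_k f_k I_ref,ik with a free overall scale s is fitted by
non-negative least squares on g_k = s f_k, and f = g / sum(g).
Detwinning solves, per connected group of reflections, the small linear
system its singles and composites define.  Merging uses Laue symmetry
-1 (Friedel pairs only — the P1 case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .cellgeom import Basis, enumerate_hkl, friedel_canonical

__all__ = [
    "TwinnedObservation",
    "TwinFractions",
    "MergeStats",
    "read_hklf",
    "write_hklf",
    "estimate_twin_fractions",
    "detwin_intensities",
    "merge_laue",
    "UnidentifiableError",
]


class UnidentifiableError(ValueError):
    """Twin fractions cannot be determined from the given observations."""


class HklfParseError(ValueError):
    pass


@dataclass(frozen=True)
class TwinnedObservation:
    """One measured intensity and the twin-lattice components it contains."""

    components: tuple  # ((h, k, l), domain) pairs, ordered
    intensity: float
    sigma: float

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("observation needs at least one component")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def is_composite(self) -> bool:
        return len(self.components) > 1


# ---------------------------------------------------------------------------
# SHELX HKLF4 / HKLF5 fixed-width I/O (3I4, F8.2, F8.2, I4)


def _format_record(hkl, intensity, sigma, batch) -> str:
    return "%4d%4d%4d%8.2f%8.2f%4d" % (*hkl, intensity, sigma, batch)


def write_hklf(observations, path, code: int = 5) -> None:
    """Write observations in SHELX HKLF4/HKLF5 fixed-width format.

    HKLF5 groups: every component but the last is written with a negative
    batch (its domain negated); the final component carries the positive
    domain number and closes the group.  Intensity and sigma are repeated
    on each record of a group.  A conventional all-zero record terminates
    the file.
    """
    if code not in (4, 5):
        raise ValueError("HKLF code must be 4 or 5")
    lines = []
    for obs in observations:
        if code == 4 and obs.is_composite:
            raise ValueError("HKLF4 cannot encode composite observations")
        comps = list(obs.components)
        for hkl, domain in comps[:-1]:
            lines.append(_format_record(hkl, obs.intensity, obs.sigma, -int(domain)))
        hkl, domain = comps[-1]
        lines.append(_format_record(hkl, obs.intensity, obs.sigma, int(domain)))
    lines.append(_format_record((0, 0, 0), 0.0, 0.0, 0))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_hklf(path, code: int = 5) -> list[TwinnedObservation]:
    """Read a SHELX HKLF4/HKLF5 fixed-width file (lossless round-trip with
    :func:`write_hklf`)."""
    if code not in (4, 5):
        raise ValueError("HKLF code must be 4 or 5")
    observations: list[TwinnedObservation] = []
    pending: list[tuple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if len(line) < 28:
                raise HklfParseError(f"{path}:{lineno}: short record ({len(line)} chars)")
            try:
                h = int(line[0:4])
                k = int(line[4:8])
                l = int(line[8:12])
                intensity = float(line[12:20])
                sigma = float(line[20:28])
                batch = int(line[28:32]) if len(line) >= 29 and line[28:32].strip() else 1
            except ValueError as exc:
                raise HklfParseError(f"{path}:{lineno}: {exc}") from exc
            if (h, k, l) == (0, 0, 0) and batch == 0:
                break  # terminator
            if batch < 0:
                if code == 4:
                    raise HklfParseError(
                        f"{path}:{lineno}: negative batch in an HKLF4 file"
                    )
                pending.append(((h, k, l), -batch))
                continue
            comps = tuple(pending + [((h, k, l), batch)])
            pending = []
            observations.append(
                TwinnedObservation(components=comps, intensity=intensity, sigma=sigma)
            )
    if pending:
        raise HklfParseError(f"{path}: file ends inside an open composite group")
    return observations


# ---------------------------------------------------------------------------
# twin fractions


@dataclass(frozen=True)
class TwinFractions:
    """Estimated per-domain fractions with uncertainties."""

    f: np.ndarray
    covariance: np.ndarray
    domains: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "f", np.asarray(self.f, float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, float))

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def ci95(self) -> np.ndarray:
        """(k, 2) array of 95% confidence intervals."""
        half = 1.959963984540054 * self.se
        return np.column_stack([self.f - half, self.f + half])


def _lookup_reference(reference, hkl, domain):
    if callable(reference):
        return float(reference(hkl, domain))
    key = (tuple(hkl), domain)
    if key in reference:
        return float(reference[key])
    can = friedel_canonical(hkl)
    for k in ((can, domain), tuple(hkl), can):
        if k in reference:
            return float(reference[k])
    raise KeyError(f"no reference intensity for {hkl} domain {domain}")


def estimate_twin_fractions(observations, reference) -> TwinFractions:
    """Constrained weighted least squares for the domain fractions.

    ``reference`` maps a component to its reference (calculated or
    ground-truth) intensity: a callable ``ref(hkl, domain)`` or a mapping
    keyed by (hkl, domain), hkl, or the Friedel-canonical hkl.  The fit
    I_i ~ s * sum_k f_k A_ik (weights 1/sigma^2) is solved by NNLS in
    g = s f and normalized, which makes the estimate invariant to any
    global scale on the references and enforces f >= 0, sum f = 1.
    Raises :class:`UnidentifiableError` for rank-deficient designs (one
    domain absent, or proportional reference columns).
    """
    observations = list(observations)
    if not observations:
        raise UnidentifiableError("no observations")
    domains = sorted({d for obs in observations for _, d in obs.components})
    k = len(domains)
    dix = {d: i for i, d in enumerate(domains)}
    A = np.zeros((len(observations), k))
    y = np.empty(len(observations))
    w = np.empty(len(observations))
    for i, obs in enumerate(observations):
        for hkl, d in obs.components:
            A[i, dix[d]] += _lookup_reference(reference, hkl, d)
        y[i] = obs.intensity
        w[i] = 1.0 / obs.sigma**2
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    yw = y * sw
    if k < 2:
        raise UnidentifiableError(
            "observations cover a single domain; fractions are not identifiable"
        )
    col_norm = np.linalg.norm(Aw, axis=0)
    if (col_norm == 0).any():
        missing = [domains[i] for i in np.where(col_norm == 0)[0]]
        raise UnidentifiableError(
            f"domain(s) {missing} never appear with a nonzero reference; "
            "fractions are not identifiable"
        )
    s = np.linalg.svd(Aw / col_norm, compute_uv=False)
    if s[-1] / s[0] < 1e-10:
        raise UnidentifiableError(
            "reference design is rank-deficient (proportional domain columns)"
        )
    g, _ = nnls(Aw, yw)
    total = g.sum()
    if total <= 0:
        raise UnidentifiableError("all fitted fractions are zero")
    f = g / total
    # delta-method covariance through the normalization g -> g/sum(g)
    cov_g = np.linalg.inv(Aw.T @ Aw)
    J = (np.eye(k) * total - g[:, None]) / total**2
    cov_f = J @ cov_g @ J.T
    return TwinFractions(f=f, covariance=cov_f, domains=tuple(domains))


# ---------------------------------------------------------------------------
# detwinning


def detwin_intensities(observations, fractions) -> pd.DataFrame:
    """Recover per-domain single intensities from singles + composites.

    Unknowns are the intensities J(hkl, domain); each observation
    contributes the equation I = sum_comp f_domain J(hkl, domain).
    Connected groups of unknowns are solved by weighted least squares
    with sigma propagation.  Rank-deficient groups are flagged
    ``singular`` (not dropped); negative solutions are retained and
    flagged ``negative``.
    """
    f = np.asarray(getattr(fractions, "f", fractions), float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    observations = list(observations)
    # union-find over unknown keys to build connected groups
    parent: dict = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    def key(hkl, d):
        return (friedel_canonical(hkl), int(d))

    for obs in observations:
        keys = [key(h, d) for h, d in obs.components]
        for a in keys[1:]:
            union(keys[0], a)
    groups: dict = {}
    for obs in observations:
        root = find(key(*obs.components[0]))
        groups.setdefault(root, []).append(obs)

    rows = []
    for members in groups.values():
        unknowns = sorted({key(h, d) for obs in members for h, d in obs.components})
        uix = {u: i for i, u in enumerate(unknowns)}
        A = np.zeros((len(members), len(unknowns)))
        y = np.empty(len(members))
        sw = np.empty(len(members))
        for i, obs in enumerate(members):
            for h, d in obs.components:
                A[i, uix[key(h, d)]] += f[int(d) - 1]
            y[i] = obs.intensity
            sw[i] = 1.0 / obs.sigma
        Aw = A * sw[:, None]
        yw = y * sw
        rank = np.linalg.matrix_rank(Aw, tol=1e-10 * max(1.0, np.abs(Aw).max()))
        singular = rank < len(unknowns)
        if singular:
            sol = np.full(len(unknowns), np.nan)
            sig = np.full(len(unknowns), np.nan)
        else:
            sol, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
            cov = np.linalg.inv(Aw.T @ Aw)
            sig = np.sqrt(np.diag(cov))
        for (hkl, d), val, s in zip(unknowns, sol, sig):
            flag = "singular" if singular else ("negative" if val < 0 else "ok")
            rows.append(
                {"h": hkl[0], "k": hkl[1], "l": hkl[2], "domain": d,
                 "intensity": val, "sigma": s, "flag": flag}
            )
    return pd.DataFrame(rows).sort_values(["domain", "h", "k", "l"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Laue -1 merging


@dataclass(frozen=True)
class MergeStats:
    """Merging statistics under Laue symmetry -1 (Friedel pairs)."""

    n_total: int
    n_unique: int
    multiplicity: float
    completeness: float | None
    r_merge: float
    r_pim: float
    cc_half: float
    i_over_sigma: float
    shells: pd.DataFrame = field(repr=False)
    unique: pd.DataFrame = field(repr=False)


def _r_stats(df: pd.DataFrame) -> tuple[float, float]:
    num_rm = num_rp = den = 0.0
    for _, grp in df.groupby("class_key"):
        if len(grp) < 2:
            continue
        I = grp["intensity"].to_numpy()
        dev = np.abs(I - I.mean()).sum()
        num_rm += dev
        num_rp += math.sqrt(1.0 / (len(I) - 1)) * dev
        den += I.sum()
    if den == 0:
        return 0.0, 0.0
    return num_rm / den, num_rp / den


def _cc_half(df: pd.DataFrame, rng) -> float:
    half1, half2 = [], []
    for _, grp in df.groupby("class_key"):
        if len(grp) < 2:
            continue
        I = grp["intensity"].to_numpy()
        perm = rng.permutation(len(I))
        cut = len(I) // 2
        half1.append(I[perm[:cut]].mean())
        half2.append(I[perm[cut:]].mean())
    if len(half1) < 2:
        return float("nan")
    return float(np.corrcoef(half1, half2)[0, 1])


def merge_laue(
    observations,
    basis: Basis | None = None,
    dmin: float | None = None,
    shells: int = 10,
    seed: int = 0,
) -> MergeStats:
    """Merge single observations under Friedel equivalence and report
    Rmerge, Rpim, CC1/2, multiplicity, I/sigma and (when a basis is
    given) completeness, overall and in ``shells`` equal-count
    resolution shells.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("no observations to merge")
    if any(obs.is_composite for obs in observations):
        raise ValueError("merging requires single-component observations "
                         "(detwin composites first)")
    recs = []
    for obs in observations:
        (hkl, domain) = obs.components[0]
        recs.append(
            {"class_key": friedel_canonical(hkl), "intensity": obs.intensity,
             "sigma": obs.sigma}
        )
    df = pd.DataFrame(recs)
    if basis is not None:
        df["d"] = [
            1.0 / np.linalg.norm(basis.reciprocal @ np.asarray(k, float))
            for k in df["class_key"]
        ]
    rng = np.random.default_rng(seed)

    n_total = len(df)
    uni = (
        df.groupby("class_key")
        .agg(intensity=("intensity", "mean"), n=("intensity", "size"),
             sigma=("sigma", lambda s: math.sqrt(float((s**2).sum())) / len(s)))
        .reset_index()
    )
    n_unique = len(uni)
    r_merge, r_pim = _r_stats(df)
    cc = _cc_half(df, rng)
    i_sig = float((uni["intensity"] / uni["sigma"]).mean())

    completeness = None
    if basis is not None:
        data_dmin = dmin if dmin is not None else float(df["d"].min())
        expected = enumerate_hkl(basis, data_dmin, friedel_unique=True)
        have = {k for k in uni["class_key"]}
        n_hit = sum(1 for h in map(tuple, expected) if friedel_canonical(h) in have)
        completeness = n_hit / len(expected) if len(expected) else float("nan")

    # equal-count resolution shells (needs d-spacings)
    if basis is not None and shells > 1 and n_unique >= shells:
        uni_sorted = uni.assign(
            d=[1.0 / np.linalg.norm(basis.reciprocal @ np.asarray(k, float))
               for k in uni["class_key"]]
        ).sort_values("d", ascending=False)
        edges = np.array_split(np.arange(len(uni_sorted)), shells)
        shell_rows = []
        for i, idx in enumerate(edges):
            sub_keys = set(uni_sorted.iloc[idx]["class_key"])
            sub = df[df["class_key"].isin(sub_keys)]
            rm, rp = _r_stats(sub)
            shell_rows.append(
                {"shell": i + 1,
                 "d_max": float(uni_sorted.iloc[idx]["d"].max()),
                 "d_min": float(uni_sorted.iloc[idx]["d"].min()),
                 "n_total": len(sub), "n_unique": len(sub_keys),
                 "multiplicity": len(sub) / len(sub_keys),
                 "r_merge": rm, "r_pim": rp,
                 "cc_half": _cc_half(sub, rng)}
            )
        shell_df = pd.DataFrame(shell_rows)
    else:
        shell_df = pd.DataFrame()
    return MergeStats(
        n_total=n_total,
        n_unique=n_unique,
        multiplicity=n_total / n_unique,
        completeness=completeness,
        r_merge=r_merge,
        r_pim=r_pim,
        cc_half=cc,
        i_over_sigma=i_sig,
        shells=shell_df,
        unique=uni,
    )
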