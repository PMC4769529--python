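"""Haplotype-copying imputation engine.

The built-in engine is a Li–Stephens copying HMM: each held-out haplotype
is modelled as an imperfect mosaic of the reference haplotypes.  Hidden
states are reference haplotypes; between sites the copied haplotype
switches with a probability that grows with inter-site distance; at typed
sites the observed allele matches the copied haplotype's allele with
probability 1 - error_rate.  Forward-backward over the typed sites gives
posterior copying probabilities, and the imputed alternate-allele
probability at an untyped site is the posterior-weighted average of the
reference alleles there.  Per-sample dosages sum the two haplotypes.

Distances use variant-index units of the reference panel (a uniform
genetic map); the per-distance switch probability is
``rho(d) = 1 - exp(-switch_rate * d)``, and a switch lands uniformly on
the reference haplotypes, so transitions compose exactly across silent
(untyped) sites.  Forward and backward vectors are rescaled per site to
avoid underflow.

Any external imputation program can stand in for the built-in engine via
:class:`ExternalCommandEngine`, which must honour the same contract:
dosages in [0, 2] and typed sites passed through as measured.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .panel_io import (
    GenotypeMatrix,
    HaplotypePanel,
    read_genotype_tsv,
    write_panel,
)


@dataclass(frozen=True, slots=True)
class HMMParams:
    """Copying-model parameters.

    switch_rate
        Haplotype-switch intensity per site of map distance.  The default
        0.01 gives roughly one expected switch per 100 consecutive typed
        sites.
    error_rate
        Allele-copy error (emission mismatch probability), in (0, 0.5).
    """

    switch_rate: float = 0.01
    error_rate: float = 0.001

    def __post_init__(self):
        if self.switch_rate <= 0:
            raise ValueError("switch_rate must be > 0")
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")


@dataclass
class DosageMatrix:
    """Imputed expected alternate-allele counts, entries in [0, 2]."""

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray  # (n_samples, n_variants)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("dosage shape inconsistent with id lists")
        if self.dosages.size and (
            self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9
        ):
            raise ValueError("dosages must lie in [0, 2]")


def _transition_blend(v: np.ndarray, rho: float) -> np.ndarray:
    """Apply the uniform-switch transition to a state-weight vector.

    For row-stochastic T with stay (1-rho)+rho/K and move rho/K, the image
    of v is (1-rho) v + rho * mean(v).
    """
    return (1.0 - rho) * v + rho * v.mean()


class LiStephensEngine:
    """Built-in Li–Stephens forward-backward imputation engine."""

    def __init__(self, params: HMMParams | None = None):
        self.params = params or HMMParams()

    def impute(
        self,
        reference: HaplotypePanel,
        held_out: HaplotypePanel,
        typed_sites,
    ) -> DosageMatrix:
        return impute_dosages(reference, held_out, typed_sites, self.params)

    # -- internals ---------------------------------------------------------

    def _haplotype_posteriors(
        self,
        ref_h: np.ndarray,
        obs: np.ndarray,
        tidx: np.ndarray,
    ) -> tuple:
        """Forward-backward for one held-out haplotype over typed sites.

        Returns (gamma, loglik_forward, loglik_backward, alpha, beta,
        emissions, rho); gamma rows sum to 1 over reference haplotypes.
        """
        e = self.params.error_rate
        K = ref_h.shape[0]
        T = len(tidx)
        # emission[t, k]
        match = ref_h[:, tidx].T == obs[None, :].T
        E = np.where(match, 1.0 - e, e)
        rho = 1.0 - np.exp(-self.params.switch_rate * np.diff(tidx))

        alpha = np.empty((T, K))
        cs = np.empty(T)
        a = E[0] / K
        cs[0] = a.sum()
        alpha[0] = a / cs[0]
        for t in range(1, T):
            pred = _transition_blend(alpha[t - 1], rho[t - 1])
            a = pred * E[t]
            cs[t] = a.sum()
            alpha[t] = a / cs[t]
        loglik_f = float(np.log(cs).sum())

        beta = np.empty((T, K))
        ds = np.empty(T)
        beta[T - 1] = 1.0
        ds[T - 1] = 1.0
        for t in range(T - 2, -1, -1):
            v = beta[t + 1] * E[t + 1]
            b = _transition_blend(v, rho[t])
            ds[t] = b.sum()
            beta[t] = b / ds[t]
        # backward likelihood: sum_k pi_k E[0,k] beta~[0,k] * prod(scales)
        loglik_b = float(
            np.log((E[0] / K * beta[0]).sum()) + np.log(ds[:-1]).sum()
        )

        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        return gamma, loglik_f, loglik_b, alpha, beta, E, rho

    def _untyped_allele_probs(
        self,
        ref_h: np.ndarray,
        obs: np.ndarray,
        tidx: np.ndarray,
        uidx: np.ndarray,
    ) -> np.ndarray:
        """Posterior alternate-allele probabilities at untyped sites."""
        gamma, _, _, alpha, beta, E, _ = self._haplotype_posteriors(
            ref_h, obs, tidx
        )
        K = ref_h.shape[0]
        c = self.params.switch_rate
        out = np.empty(len(uidx))
        # right factors at typed sites: beta~[t] * E[t] (scale irrelevant)
        right_typed = beta * E
        seg = np.searchsorted(tidx, uidx)  # number of typed sites to the left
        for n, (u, s) in enumerate(zip(uidx, seg)):
            if s == 0:  # before the first typed site
                rho = 1.0 - np.exp(-c * (tidx[0] - u))
                g = _transition_blend(right_typed[0], rho)  # uniform prior
            elif s == len(tidx):  # after the last typed site
                rho = 1.0 - np.exp(-c * (u - tidx[-1]))
                g = _transition_blend(alpha[-1], rho)
            else:
                rho_l = 1.0 - np.exp(-c * (u - tidx[s - 1]))
                rho_r = 1.0 - np.exp(-c * (tidx[s] - u))
                left = _transition_blend(alpha[s - 1], rho_l)
                right = _transition_blend(right_typed[s], rho_r)
                g = left * right
            g = g / g.sum()
            out[n] = float(g @ ref_h[:, u])
        return out


def impute_dosages(
    reference: HaplotypePanel,
    held_out: HaplotypePanel,
    typed_sites,
    params: HMMParams | None = None,
) -> DosageMatrix:
    """Impute dosages at all reference sites for held-out samples.

    ``held_out`` carries phased haplotypes over (at least) the typed
    sites; ``typed_sites`` must be a subset of the reference variants.
    Typed sites are passed through as the measured genotypes; untyped
    sites get posterior dosages from the copying model.

    Raises
    ------
    ValueError
        If typed_sites is empty, the reference has fewer than 2
        haplotypes, or a held-out sample also appears in the reference.
    """
    params = params or HMMParams()
    typed = list(dict.fromkeys(typed_sites))
    if not typed:
        raise ValueError("typed_sites must not be empty")
    if 2 * reference.n_samples < 2:
        raise ValueError("reference must contain at least 2 haplotypes")
    overlap = set(held_out.sample_ids) & set(reference.sample_ids)
    if overlap:
        raise ValueError(
            f"held-out samples present in reference: {sorted(overlap)[:3]}"
        )

    ref_ids = reference.variant_ids
    tset = set(typed)
    missing = tset - set(ref_ids)
    if missing:
        raise ValueError(f"typed sites absent from reference: {sorted(missing)[:3]}")
    tidx = np.asarray(sorted(reference.variant_index(v) for v in typed), dtype=np.intp)
    typed_idx_set = set(tidx.tolist())
    uidx = np.asarray(
        [i for i in range(reference.n_variants) if i not in typed_idx_set],
        dtype=np.intp,
    )

    ref_h = reference.haplotypes
    engine = LiStephensEngine(params)

    n = held_out.n_samples
    m = reference.n_variants
    dosages = np.zeros((n, m))

    # typed-site pass-through, in reference order
    typed_ids_sorted = [ref_ids[i] for i in tidx]
    ho_cols = np.asarray(
        [held_out.variant_index(v) for v in typed_ids_sorted], dtype=np.intp
    )
    geno_typed = held_out.genotypes()[:, ho_cols]  # (n, T)
    dosages[:, tidx] = geno_typed

    if uidx.size:
        for i in range(n):
            for hap_row in (2 * i, 2 * i + 1):
                obs = held_out.haplotypes[hap_row, ho_cols]
                dosages[i, uidx] += engine._untyped_allele_probs(
                    ref_h, obs, tidx, uidx
                )

    return DosageMatrix(
        sample_ids=list(held_out.sample_ids),
        variant_ids=list(ref_ids),
        dosages=np.clip(dosages, 0.0, 2.0),
    )


def validate_dosage_contract(
    dm: DosageMatrix,
    held_out: HaplotypePanel,
    typed_sites,
    atol: float = 1e-9,
) -> None:
    """Check the engine contract: bounds and typed-site pass-through.

    Raises ValueError on violation.  Used to vet external engines.
    """
    if dm.dosages.size and (dm.dosages.min() < -atol or dm.dosages.max() > 2 + atol):
        raise ValueError("dosages out of [0, 2]")
    vidx = {v: i for i, v in enumerate(dm.variant_ids)}
    geno = held_out.genotypes()
    sidx = {s: i for i, s in enumerate(held_out.sample_ids)}
    for v in typed_sites:
        if v not in vidx:
            continue
        col = dm.dosages[:, vidx[v]]
        meas = geno[[sidx[s] for s in dm.sample_ids], held_out.variant_index(v)]
        if not np.allclose(col, meas, atol=atol):
            raise ValueError(f"typed site {v!r} not passed through as measured")


class ExternalCommandEngine:
    """Adapter running an external imputation program.

    The command template receives ``{reference}`` (VCF), ``{typed}``
    (VCF restricted to typed sites), ``{sites}`` (one typed id per line)
    and ``{out}`` (dosage TSV the program must write: marker rows, sample
    columns).  The returned matrix is checked against the same contract
    as the built-in engine.
    """

    def __init__(self, command_template: str):
        self.command_template = command_template

    def impute(
        self,
        reference: HaplotypePanel,
        held_out: HaplotypePanel,
        typed_sites,
    ) -> DosageMatrix:
        typed = list(dict.fromkeys(typed_sites))
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            write_panel(reference, tmp / "reference.vcf")
            write_panel(held_out.subset_variants(typed), tmp / "typed.vcf")
            (tmp / "sites.txt").write_text("\n".join(typed) + "\n")
            out = tmp / "dosages.tsv"
            cmd = self.command_template.format(
                reference=tmp / "reference.vcf",
                typed=tmp / "typed.vcf",
                sites=tmp / "sites.txt",
                out=out,
            )
            subprocess.run(cmd, shell=True, check=True)
            gm = read_dosage_tsv(out)
        dm = DosageMatrix(
            sample_ids=gm[0], variant_ids=gm[1], dosages=gm[2]
        )
        validate_dosage_contract(dm, held_out, typed)
        return dm


def read_dosage_tsv(path):
    """Read a dosage TSV (marker rows, sample columns) -> ids and matrix."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return (
        [str(c) for c in df.columns],
        [str(i) for i in df.index],
        df.to_numpy(dtype=float).T,
    )
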