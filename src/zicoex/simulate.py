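"""Multi-patient two-gene count simulator.

Generation follows the model's own mechanism: draw patient-level random
intercepts, form per-cell natural parameters through the links, draw a
standard bivariate Gaussian pair with the cell's correlation, push each
coordinate through the NBII quantile function, and apply independent
Bernoulli dropout.

Two presets mirror the calibration of the droplet (10x-style; shallow
depth, low over-dispersion, sparse) and plate (Smart-seq2-style; deep,
over-dispersed) regimes, with constant offsets log(3e4) and log(5e5)
respectively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr

from .copula import CellParams, nb_quantile
from .data import GenePairData

__all__ = ["ScenarioPreset", "SimulatedDataset", "droplet_preset",
           "plate_preset", "simulate"]


@dataclass(frozen=True)
class ScenarioPreset:
    """Fixed-effect calibration plus design of a two-group simulation.

    b0j/b1j: intercept/group effect on log mean of gene j.
    a0j/a1j: intercept/group effect on log over-dispersion of gene j.
    tau0/tau1: intercept/group effect on atanh co-expression; tau1 is the
    differential co-expression parameter.
    p0j/p1j: dropout probability of gene j in group 0, and its increment in
    group 1, on the probability scale (group-1 dropout is p0j + p1j).
    log_depth: constant log sequencing depth (offset).
    re_sd: random-intercept standard deviation per parameter (patient level).
    group_rule: 'within_patient_half' assigns half of each patient's cells
    to each group; 'cell_bernoulli' splits cells 50/50 at random.
    """

    name: str
    b01: float; b11: float; b02: float; b12: float
    a01: float; a11: float; a02: float; a12: float
    tau0: float; tau1: float
    p01: float; p11: float; p02: float; p12: float
    log_depth: float = np.log(3e4)
    re_sd: dict = field(default_factory=lambda: {
        "mu1": 0.2, "mu2": 0.2, "rho": 0.2, "p1": 0.1, "p2": 0.1})
    n_patients: int = 10
    cells_per_patient: int = 250
    group_rule: str = "within_patient_half"

    def with_(self, **kw) -> "ScenarioPreset":
        return replace(self, **kw)


def droplet_preset(**overrides) -> ScenarioPreset:
    """Droplet-regime calibration; offset log(3e4)."""
    p = ScenarioPreset(
        name="droplet",
        b01=-7.26, b11=0.45, b02=-7.10, b12=0.20,
        a01=-0.46, a11=-0.19, a02=-0.44, a12=-0.04,
        tau0=0.06, tau1=-0.20,
        p01=0.01, p11=0.05, p02=0.01, p12=0.01,
        log_depth=float(np.log(3e4)),
        group_rule="within_patient_half")
    return p.with_(**overrides) if overrides else p


def plate_preset(**overrides) -> ScenarioPreset:
    """Plate-regime calibration; offset log(5e5)."""
    p = ScenarioPreset(
        name="plate",
        b01=-7.43, b11=-1.26, b02=-8.26, b12=-0.65,
        a01=0.51, a11=0.65, a02=0.85, a12=0.26,
        tau0=0.35, tau1=-0.34,
        p01=0.08, p11=0.14, p02=0.11, p12=0.21,
        log_depth=float(np.log(5e5)),
        group_rule="cell_bernoulli")
    return p.with_(**overrides) if overrides else p


@dataclass
class SimulatedDataset:
    """Counts plus full ground truth of one simulated two-gene study."""

    counts: np.ndarray          # (cells, 2) integer counts
    patient: np.ndarray
    group: np.ndarray           # 0/1 indicator
    depth: np.ndarray
    truth: CellParams           # per-cell natural parameters
    random_effects: dict        # parameter -> per-patient draws
    preset: ScenarioPreset
    seed: int

    def to_pair_data(self) -> GenePairData:
        return GenePairData(
            y1=self.counts[:, 0], y2=self.counts[:, 1], patient=self.patient,
            covariates=pd.DataFrame({"group": self.group}), depth=self.depth,
            gene_names=("gene1", "gene2"))

    def write(self, outdir, fmt: str = "tsv") -> None:
        """Write counts (TSV or MTX triplet), metadata TSV, truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cells = [f"cell{i:05d}" for i in range(len(self.patient))]
        meta = pd.DataFrame({
            "cell_id": cells, "patient": self.patient, "group": self.group,
            "depth": self.depth})
        meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        mat = pd.DataFrame(self.counts.T, index=["gene1", "gene2"],
                           columns=cells)
        if fmt == "tsv":
            mat.to_csv(outdir / "counts.tsv", sep="\t")
        elif fmt == "mtx":
            from scipy import io as spio
            from scipy import sparse
            spio.mmwrite(str(outdir / "matrix.mtx"),
                         sparse.csr_matrix(self.counts.T.astype(int)))
            pd.Series(["gene1", "gene2"]).to_csv(
                outdir / "features.tsv", sep="\t", index=False, header=False)
            pd.Series(cells).to_csv(
                outdir / "barcodes.tsv", sep="\t", index=False, header=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        manifest = {
            "preset": self.preset.name, "seed": self.seed,
            "n_patients": int(self.preset.n_patients),
            "cells_per_patient": int(self.preset.cells_per_patient),
            "tau0": self.preset.tau0, "tau1": self.preset.tau1,
            "random_effects": {k: list(map(float, v))
                               for k, v in self.random_effects.items()},
        }
        (outdir / "truth.json").write_text(json.dumps(manifest, indent=1))


def _safe_logit(p):
    return logit(np.clip(p, 1e-12, 1 - 1e-12))


def simulate(preset: ScenarioPreset, seed: int = 0) -> SimulatedDataset:
    """Generate one dataset; a fixed seed gives bit-identical output.

    Per-patient RNG substreams are spawned deterministically from the seed,
    so changing the number of patients leaves earlier patients' cells
    unchanged.
    """
    m = int(preset.n_patients)
    npc = int(preset.cells_per_patient)
    if m < 1 or npc < 1:
        raise ValueError("need at least one patient and one cell")
    if preset.group_rule not in ("within_patient_half", "cell_bernoulli"):
        raise ValueError(f"unknown group rule {preset.group_rule!r}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(m)
    re_params = ("mu1", "mu2", "rho", "p1", "p2")
    re_draws = {t: np.zeros(m) for t in re_params}
    counts = np.zeros((m * npc, 2), dtype=np.int64)
    patient = np.repeat([f"P{k + 1:02d}" for k in range(m)], npc)
    group = np.zeros(m * npc, dtype=int)
    truth = {k: np.zeros(m * npc) for k in
             ("mu1", "mu2", "sigma1", "sigma2", "rho", "p1", "p2")}
    S = float(np.exp(preset.log_depth))

    for k in range(m):
        rng = np.random.default_rng(children[k])
        for t in re_params:
            re_draws[t][k] = rng.normal(0.0, preset.re_sd.get(t, 0.0))
        sl = slice(k * npc, (k + 1) * npc)
        if preset.group_rule == "within_patient_half":
            x = np.zeros(npc, dtype=int)
            x[npc // 2:] = 1
        else:
            x = (rng.random(npc) < 0.5).astype(int)
        group[sl] = x
        mu1 = np.exp(preset.b01 + preset.b11 * x + re_draws["mu1"][k]
                     + preset.log_depth)
        mu2 = np.exp(preset.b02 + preset.b12 * x + re_draws["mu2"][k]
                     + preset.log_depth)
        s1 = np.exp(preset.a01 + preset.a11 * x)
        s2 = np.exp(preset.a02 + preset.a12 * x)
        rho = np.tanh(preset.tau0 + preset.tau1 * x + re_draws["rho"][k])
        p1_base = preset.p01 + preset.p11 * x
        p2_base = preset.p02 + preset.p12 * x
        # zero stays exactly zero; otherwise the patient effect acts on the
        # logit scale around the preset probability
        p1 = np.where(p1_base > 0,
                      expit(_safe_logit(p1_base) + re_draws["p1"][k]), 0.0)
        p2 = np.where(p2_base > 0,
                      expit(_safe_logit(p2_base) + re_draws["p2"][k]), 0.0)
        z1 = rng.standard_normal(npc)
        z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(npc)
        v1 = nb_quantile(ndtr(z1), mu1, s1)
        v2 = nb_quantile(ndtr(z2), mu2, s2)
        drop1 = rng.random(npc) < p1
        drop2 = rng.random(npc) < p2
        counts[sl, 0] = np.where(drop1, 0, v1)
        counts[sl, 1] = np.where(drop2, 0, v2)
        for name, arr in (("mu1", mu1), ("mu2", mu2), ("sigma1", s1),
                          ("sigma2", s2), ("rho", rho), ("p1", p1),
                          ("p2", p2)):
            truth[name][sl] = arr

    return SimulatedDataset(
        counts=counts, patient=patient, group=group,
        depth=np.full(m * npc, S), truth=CellParams(**truth),
        random_effects=re_draws, preset=preset, seed=seed)
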