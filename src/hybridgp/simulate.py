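"""Synthetic dataset generation: inbred parents, a replicated metabolome
partially under genetic control, a sparse partial diallel of hybrids, and
traits with additive + dominance + metabolite-mediated architecture.

Ground truth (causal loci, causal metabolites, realized heritability) is
recorded so recovery tests can check every pipeline stage. The metabolite
contribution to the trait acts through the line-level metabolite values --
including their non-genetic component -- so metabolite features can carry
trait signal beyond what the SNP panel explains.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    CrossTable,
    GenotypeMatrix,
    MetabolomeMatrix,
    PhenotypeTable,
    write_crosses,
    write_genotypes,
    write_metabolome,
    write_phenotypes,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_parents",
    "simulate_metabolome",
    "simulate_hybrids_and_trait",
    "simulate_bundle",
    "write_bundle",
]


@dataclass
class SimulationConfig:
    n_parents: int = 100
    g: int = 500
    m: int = 200
    n_replicates: int = 2
    n_hybrids: int = 300
    n_qtl: int = 20
    metabolite_genetic_fraction: float = 0.5
    metabolite_h2: float = 0.6
    snps_per_metabolite: int = 10
    trait_h2: float = 0.6
    dominance_fraction: float = 0.2
    n_causal_metabolites: int = 5
    metabolite_signal_fraction: float = 0.3
    replicate_noise_sd: float = 0.1
    trait_name: str = "trait1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "metabolite_genetic_fraction",
            "metabolite_h2",
            "trait_h2",
            "dominance_fraction",
            "metabolite_signal_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        max_hybrids = self.n_parents * (self.n_parents - 1) // 2
        if self.n_hybrids > max_hybrids:
            raise ValueError(f"n_hybrids exceeds the diallel size {max_hybrids}")
        if self.g < self.n_qtl:
            raise ValueError("fewer SNPs than QTL")
        if self.m < self.n_causal_metabolites:
            raise ValueError("fewer metabolites than causal metabolites")
        if self.trait_h2 >= 1.0 and self.trait_h2 != 1.0:
            raise ValueError("infeasible heritability")


@dataclass
class TruthRecord:
    causal_snp_ids: list[str] = field(default_factory=list)
    additive_effects: list[float] = field(default_factory=list)
    dominance_effects: list[float] = field(default_factory=list)
    causal_metabolite_ids: list[str] = field(default_factory=list)
    metabolite_effects: list[float] = field(default_factory=list)
    genetic_metabolite_ids: list[str] = field(default_factory=list)
    realized_h2: float | None = None
    variance_components: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def simulate_parents(config: SimulationConfig) -> GenotypeMatrix:
    """Fully inbred parents with codes in {-1, +1}; per-marker allele
    frequency drawn Uniform(0.1, 0.9)."""
    rng = np.random.default_rng([config.seed, 1])
    freq = rng.uniform(0.1, 0.9, size=config.g)
    codes = np.where(rng.random((config.n_parents, config.g)) < freq, 1.0, -1.0)
    line_ids = [f"L{i:04d}" for i in range(config.n_parents)]
    marker_ids = [f"snp{j:05d}" for j in range(config.g)]
    return GenotypeMatrix(line_ids, marker_ids, codes)


def simulate_metabolome(
    G: GenotypeMatrix, config: SimulationConfig
) -> tuple[MetabolomeMatrix, TruthRecord]:
    """Replicated intensities; a fraction of metabolites is a linear
    function of a few SNPs plus line-level noise, the rest pure noise."""
    rng = np.random.default_rng([config.seed, 2])
    n, g, m = G.n_lines, G.n_markers, config.m
    n_gen = int(round(config.metabolite_genetic_fraction * m))
    latent = rng.standard_normal((n, m))
    gen_ids = []
    for j in range(n_gen):
        snps = rng.choice(g, size=min(config.snps_per_metabolite, g), replace=False)
        w = rng.standard_normal(snps.size)
        gval = G.codes[:, snps] @ w
        s = gval.std()
        if s > 0:
            gval = gval / s
        h = config.metabolite_h2
        latent[:, j] = np.sqrt(h) * gval + np.sqrt(1.0 - h) * rng.standard_normal(n)
        gen_ids.append(j)
    metabolite_ids = [f"m{j:04d}" for j in range(m)]
    # shift to positive raw intensities; replicate rows interleaved per line
    offset = float(np.abs(latent).max()) + 6.0 * config.replicate_noise_sd + 1.0
    rows, line_col, rep_col = [], [], []
    for i, lid in enumerate(G.line_ids):
        for r in range(config.n_replicates):
            noise = (
                rng.standard_normal(m) * config.replicate_noise_sd
                if config.replicate_noise_sd > 0
                else np.zeros(m)
            )
            rows.append(latent[i] + offset + noise)
            line_col.append(lid)
            rep_col.append(f"r{r + 1}")
    values = np.clip(np.vstack(rows), 0.0, None)
    meta = pd.DataFrame(
        {
            "annotation": [f"compound_{j}" for j in range(m)],
            "category": np.where(np.arange(m) < n_gen, "genetic", "environmental"),
            "tissue": "leaf",
        },
        index=metabolite_ids,
    )
    truth = TruthRecord(genetic_metabolite_ids=[metabolite_ids[j] for j in gen_ids])
    return (
        MetabolomeMatrix(line_col, metabolite_ids, values, replicate_index=rep_col, meta=meta),
        truth,
    )


def _line_latents(Mx: MetabolomeMatrix) -> pd.DataFrame:
    df = Mx.to_frame()
    if Mx.replicate_index is not None:
        df.index = pd.Index(Mx.line_ids, name="line")
        df = df.groupby(level="line", sort=True).mean()
    return df


def simulate_hybrids_and_trait(
    G: GenotypeMatrix,
    Mline: MetabolomeMatrix,
    config: SimulationConfig,
    truth: TruthRecord | None = None,
) -> tuple[CrossTable, PhenotypeTable, PhenotypeTable, TruthRecord]:
    """Sample a sparse partial diallel and generate parental plus hybrid
    phenotypes with additive, dominance, and metabolite-mediated signal
    scaled to the target heritability."""
    rng = np.random.default_rng([config.seed, 3])
    truth = truth or TruthRecord()
    n = G.n_lines

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pick = rng.choice(len(pairs), size=config.n_hybrids, replace=False)
    crosses = CrossTable.from_records(
        [
            (f"H{t:04d}", G.line_ids[pairs[p][0]], G.line_ids[pairs[p][1]])
            for t, p in enumerate(np.sort(pick))
        ]
    )
    fi = [G.line_ids.index(p) for p in crosses.table["parent_female"]]
    mi = [G.line_ids.index(p) for p in crosses.table["parent_male"]]

    qtl = np.sort(rng.choice(config.g, size=config.n_qtl, replace=False))
    a_eff = rng.standard_normal(config.n_qtl)
    d_eff = np.abs(rng.standard_normal(config.n_qtl))
    Zq_h = (G.codes[fi][:, qtl] + G.codes[mi][:, qtl]) / 2.0
    het_h = 1.0 - np.abs(Zq_h)  # 1 where the parents carry opposite alleles
    Zq_p = G.codes[:, qtl]

    metab = _line_latents(Mline)
    metab_z = (metab - metab.mean()) / metab.std().replace(0.0, 1.0)
    causal = np.sort(rng.choice(Mline.n_metabolites, size=config.n_causal_metabolites, replace=False))
    m_eff = rng.standard_normal(config.n_causal_metabolites)
    Mc = metab_z.iloc[:, causal].to_numpy()
    A_c = (Mc[fi] + Mc[mi]) / 2.0

    def unitize(x: np.ndarray) -> tuple[np.ndarray, float]:
        s = x.std()
        return (x / s, s) if s > 0 else (x, 1.0)

    add_h, s_add = unitize(Zq_h @ a_eff)
    dom_raw = het_h @ d_eff
    dom_h, s_dom = unitize(dom_raw - dom_raw.mean())
    met_h, s_met = unitize(A_c @ m_eff)

    mf, df_ = config.metabolite_signal_fraction, config.dominance_fraction
    w_add = np.sqrt((1.0 - mf) * (1.0 - df_))
    w_dom = np.sqrt((1.0 - mf) * df_)
    w_met = np.sqrt(mf)
    signal_h = w_add * add_h + w_dom * dom_h + w_met * met_h
    sv = signal_h.var()
    h2 = config.trait_h2
    if h2 == 0:
        y_h = rng.standard_normal(config.n_hybrids)
    else:
        noise_var = sv * (1.0 - h2) / h2 if h2 < 1 else 0.0
        y_h = signal_h + rng.standard_normal(config.n_hybrids) * np.sqrt(noise_var)
    realized = float(signal_h.var() / y_h.var()) if y_h.var() > 0 and h2 > 0 else 0.0

    # parental phenotypes from the same effects on parental features
    add_p = (Zq_p @ a_eff) / s_add
    met_p = (metab_z.iloc[:, causal].to_numpy() @ m_eff) / s_met
    signal_p = w_add * add_p + w_met * met_p  # inbreds carry no heterozygosity
    if h2 == 0:
        y_p = rng.standard_normal(n)
    else:
        noise_var_p = signal_p.var() * (1.0 - h2) / h2 if h2 < 1 else 0.0
        y_p = signal_p + rng.standard_normal(n) * np.sqrt(noise_var_p)

    truth.causal_snp_ids = [G.marker_ids[j] for j in qtl]
    truth.additive_effects = (a_eff * w_add / s_add).tolist()
    truth.dominance_effects = (d_eff * w_dom / s_dom).tolist()
    truth.causal_metabolite_ids = [Mline.metabolite_ids[j] for j in causal]
    truth.metabolite_effects = (m_eff * w_met / s_met).tolist()
    truth.realized_h2 = realized
    truth.variance_components = {
        "additive": float(w_add**2),
        "dominance": float(w_dom**2),
        "metabolite": float(w_met**2),
        "noise": float(y_h.var() - signal_h.var()) if h2 > 0 else 1.0,
    }
    parent_pheno = PhenotypeTable(list(metab_z.index), [config.trait_name], y_p.reshape(-1, 1))
    hybrid_pheno = PhenotypeTable(crosses.hybrid_ids, [config.trait_name], y_h.reshape(-1, 1))
    return crosses, parent_pheno, hybrid_pheno, truth


def simulate_bundle(config: SimulationConfig):
    """Generate the full dataset: (G, metabolome, crosses, parental
    phenotypes, hybrid phenotypes, truth)."""
    G = simulate_parents(config)
    Mx, truth = simulate_metabolome(G, config)
    crosses, y_p, y_h, truth = simulate_hybrids_and_trait(G, Mx, config, truth)
    return G, Mx, crosses, y_p, y_h, truth


def write_bundle(config: SimulationConfig, directory: str | Path) -> dict[str, str]:
    """Write a ready-to-run dataset directory in the delimited dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    G, Mx, crosses, y_p, y_h, truth = simulate_bundle(config)
    paths = {
        "genotypes": str(directory / "genotypes.tsv"),
        "metabolome": str(directory / "metabolome.tsv"),
        "metabolite_meta": str(directory / "metabolite_meta.tsv"),
        "parent_phenotypes": str(directory / "phenotypes_parents.tsv"),
        "hybrid_phenotypes": str(directory / "phenotypes_hybrids.tsv"),
        "crosses": str(directory / "crosses.tsv"),
        "truth": str(directory / "truth.json"),
    }
    write_genotypes(G, paths["genotypes"])
    write_metabolome(Mx, paths["metabolome"], meta_path=paths["metabolite_meta"])
    write_phenotypes(y_p, paths["parent_phenotypes"])
    write_phenotypes(y_h, paths["hybrid_phenotypes"])
    write_crosses(crosses, paths["crosses"])
    Path(paths["truth"]).write_text(truth.to_json())
    return paths
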