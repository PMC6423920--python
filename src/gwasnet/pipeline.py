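"""End-to-end pipeline: map SNPs to genes, prune LD, score gene sets per
mapping and trait, intersect significant sets across traits, merge them
into supersets, confirm, run key-driver analysis per network, and
estimate subnetwork heritability — all from one YAML configuration with
a mandatory master seed.

Every permutation stage draws an independent substream derived
deterministically from the master seed, so a rerun with the same config
and seed reproduces every output byte-for-byte; the run manifest records
a SHA-256 per output plus the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import io as gio
from . import mapping as gmap
from .heritability import gwas_hits_h2, kd_subnetwork_h2_test, set_h2
from .kda import KeyDriverAnalysis, essential_gene_enrichment
from .msea import MSEA, flag_shared_across_mappings
from .supersets import annotate_supersets, confirm_supersets, merge_gene_sets

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

_DEFAULT_THRESHOLDS = {
    "maf_min": 0.01,
    "window_bp": 50_000,
    "eqtl_fdr_max": 0.05,
    "eqtl_p_max": 1e-5,
    "r2_max": 0.7,
    "min_set_size": 10,
    "msea_fdr_max": 0.05,
    "kda_fdr_max": 0.01,
    "kda_top_k": 5,
    "kda_depth": 1,
    "kda_min_neighbors": 5,
    "overlap_min": 0.33,
    "fisher_alpha": 0.05,
    "confirm_alpha": 0.05,
    "hits_p_max": 5e-8,
}

_DEFAULT_N_PERM = {"msea": 10_000, "kda": 10_000, "h2": 10_000}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in the message."""


@dataclass
class RunConfig:
    """Validated run configuration.

    ``traits`` maps trait name to a GWAS summary TSV; all other inputs
    are shared across traits.  ``seed`` is mandatory.
    """

    traits: dict[str, str]
    gene_annotation: str
    gene_sets: str
    ld_matrix: str
    ld_snplist: str
    output_dir: str
    seed: int
    n: int
    networks: dict[str, str] = field(default_factory=dict)
    eqtl: str | None = None
    essential_genes: str | None = None
    extra_mappings: dict[str, str] = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    n_perm: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = gio.read_config(path)
        base = os.path.dirname(os.path.abspath(str(path)))

        def resolve(p):
            return p if os.path.isabs(p) else os.path.join(base, p)

        if "seed" not in raw:
            raise gio.FormatError("config must declare a seed")
        ld = raw.get("ld", {})
        cfg = cls(
            traits={k: resolve(v) for k, v in raw["traits"].items()},
            gene_annotation=resolve(raw["gene_annotation"]),
            gene_sets=resolve(raw["gene_sets"]),
            ld_matrix=resolve(ld["matrix"]),
            ld_snplist=resolve(ld["snplist"]),
            output_dir=resolve(raw["output_dir"]),
            seed=int(raw["seed"]),
            n=int(raw["n"]),
            networks={k: resolve(v) for k, v in raw.get("networks", {}).items()},
            eqtl=resolve(raw["eqtl"]) if raw.get("eqtl") else None,
            essential_genes=resolve(raw["essential_genes"]) if raw.get("essential_genes") else None,
            extra_mappings={k: resolve(v) for k, v in raw.get("extra_mappings", {}).items()},
            thresholds=dict(raw.get("thresholds", {})),
            n_perm=dict(raw.get("n_perm", {})),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.gene_annotation, self.gene_sets, self.ld_matrix, self.ld_snplist]
        paths += list(self.traits.values()) + list(self.networks.values())
        paths += list(self.extra_mappings.values())
        if self.eqtl:
            paths.append(self.eqtl)
        if self.essential_genes:
            paths.append(self.essential_genes)
        for p in paths:
            if not os.path.exists(p):
                raise gio.FormatError(f"configured input does not exist: {p}")
        unknown = set(self.thresholds) - set(_DEFAULT_THRESHOLDS)
        if unknown:
            raise gio.FormatError(f"unknown threshold keys: {sorted(unknown)}")

    def thr(self, key: str):
        return self.thresholds.get(key, _DEFAULT_THRESHOLDS[key])

    def perms(self, stage: str) -> int:
        return int(self.n_perm.get(stage, _DEFAULT_N_PERM[stage]))


def _sub_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> str:
    """Run every stage; returns the output directory.

    Stage outputs are TSV/GMT files named after the stage; a failure
    leaves partial outputs plus a FAILED marker naming the stage.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    stage = "setup"
    try:
        genes = gmap.read_gene_annotation(config.gene_annotation)
        sets = gio.read_gene_sets_gmt(config.gene_sets, min_size=config.thr("min_set_size"))
        ld = gio.read_ld(config.ld_matrix, mode="blocks", snplist_path=config.ld_snplist)
        networks = {
            name: gio.read_network_edges(path, name=name)
            for name, path in config.networks.items()
        }
        eqtls = gmap.read_eqtl_table(config.eqtl) if config.eqtl else None

        results_by_trait: dict[str, dict[str, MSEA]] = {}
        sig_by_trait: dict[str, set[str]] = {}
        gwas_by_trait = {}
        combined_by_trait = {}
        universe: set[str] = set()
        for t_i, (trait, gwas_path) in enumerate(sorted(config.traits.items())):
            stage = f"map[{trait}]"
            gwas = gio.read_gwas_summary(gwas_path)
            gwas = gmap.filter_snps_by_maf(gwas, config.thr("maf_min"))
            gwas_by_trait[trait] = gwas
            mappings: dict[str, gmap.SnpGeneMap] = {
                "distance": gmap.map_by_distance(gwas, genes, config.thr("window_bp"))
            }
            if eqtls is not None:
                mappings["eqtl"] = gmap.map_by_eqtl(
                    eqtls, mode="significant", fdr_max=config.thr("eqtl_fdr_max")
                )
            for name, path in sorted(config.extra_mappings.items()):
                mappings[name] = gmap.read_snp_gene_map(path, source=name)
            mappings["combined"] = gmap.combine_mappings(list(mappings.values()))
            combined_by_trait[trait] = mappings["combined"]
            gmap.write_snp_gene_map(
                mappings["combined"], os.path.join(out, f"mapping_combined_{trait}.tsv")
            )
            stage = f"msea[{trait}]"
            per_map = {}
            for m_i, (mname, m) in enumerate(sorted(mappings.items())):
                model = MSEA(
                    gwas, m, sets, ld=ld, r2_max=config.thr("r2_max")
                )
                res = model.fit(
                    n_perm=config.perms("msea"),
                    seed=_sub_seed(config.seed, 1, t_i, m_i),
                )
                res.to_tsv(
                    os.path.join(out, f"msea_{trait}_{mname}.tsv"),
                    fdr_max=config.thr("msea_fdr_max"),
                )
                per_map[mname] = res
                universe |= set(model.assignment.universe)
            results_by_trait[trait] = per_map
            sig_by_trait[trait] = flag_shared_across_mappings(
                per_map, config.thr("msea_fdr_max")
            )

        stage = "shared_sets"
        shared = set.intersection(*sig_by_trait.values()) if sig_by_trait else set()
        with open(os.path.join(out, "shared_sets.tsv"), "w") as fh:
            fh.write("set_id\t" + "\t".join(sorted(sig_by_trait)) + "\n")
            for sid in sorted(shared):
                fh.write(sid + "\t" + "\t".join("1" for _ in sig_by_trait) + "\n")

        stage = "supersets"
        supersets = []
        if shared:
            shared_coll = sets.subset(sorted(s for s in shared if s in sets))
            supersets = merge_gene_sets(
                shared_coll,
                universe=universe,
                overlap_min=config.thr("overlap_min"),
                fisher_alpha=config.thr("fisher_alpha"),
            )
            supersets = annotate_supersets(supersets, sets, universe)
            from .supersets import supersets_to_collection

            gio.write_gene_sets_gmt(
                supersets_to_collection(supersets), os.path.join(out, "supersets.gmt")
            )
            with open(os.path.join(out, "superset_members.tsv"), "w") as fh:
                fh.write("superset_id\tmember_set_ids\tn_genes\ttop_annotation\tannotation_p\n")
                for ss in supersets:
                    top = ss.annotations[0] if ss.annotations else ("", "", "")
                    fh.write(
                        f"{ss.superset_id}\t{','.join(ss.member_set_ids)}\t{len(ss.genes)}"
                        f"\t{top[0]}\t{top[1]}\n"
                    )

        confirmed_ids: set[str] = set()
        if supersets:
            stage = "confirm"
            for t_i, trait in enumerate(sorted(config.traits)):
                conf = confirm_supersets(
                    supersets,
                    gwas_by_trait[trait],
                    combined_by_trait[trait],
                    ld=ld,
                    n_perm=config.perms("msea"),
                    seed=_sub_seed(config.seed, 2, t_i),
                    alpha=config.thr("confirm_alpha"),
                )
                conf.to_csv(os.path.join(out, f"supersets_confirm_{trait}.tsv"), sep="\t", index=False)
                confirmed_ids |= set(conf.loc[conf["confirmed"], "set_id"])

        stage = "kda"
        all_kds: set[str] = set()
        kd_subnets: dict[str, set[str]] = {}
        from .supersets import supersets_to_collection

        target_sets = (
            {ss.superset_id: set(ss.genes) for ss in supersets if ss.superset_id in confirmed_ids}
            if supersets
            else {}
        )
        for n_i, (nname, net) in enumerate(sorted(networks.items())):
            for s_i, (sid, sgenes) in enumerate(sorted(target_sets.items())):
                model = KeyDriverAnalysis(
                    net,
                    sgenes,
                    depth=config.thr("kda_depth"),
                    min_neighbors=config.thr("kda_min_neighbors"),
                )
                res = model.fit(
                    n_perm=config.perms("kda"),
                    seed=_sub_seed(config.seed, 3, n_i, s_i),
                    fdr_max=config.thr("kda_fdr_max"),
                    top_k=config.thr("kda_top_k"),
                )
                frame = res.frame.copy()
                frame.insert(2, "superset_id", sid)
                frame.to_csv(
                    os.path.join(out, f"kda_{nname}_{sid}.tsv"), sep="\t", index=False
                )
                for sn in res.subnetworks:
                    all_kds.add(sn.kd_gene)
                    kd_subnets.setdefault(nname, set()).update(sn.member_genes)

        if config.essential_genes and all_kds:
            stage = "essential"
            with open(config.essential_genes) as fh:
                essential = {line.strip() for line in fh if line.strip()}
            net_universe = set().union(*(net.nodes for net in networks.values()))
            odds, p = essential_gene_enrichment(all_kds, essential, net_universe)
            with open(os.path.join(out, "kd_essential_enrichment.tsv"), "w") as fh:
                fh.write("n_kds\todds_ratio\tfisher_p\n")
                fh.write(f"{len(all_kds)}\t{odds:.6g}\t{p:.6g}\n")

        stage = "heritability"
        with open(os.path.join(out, "heritability.tsv"), "w") as fh:
            fh.write("trait\tlabel\th2\tse\tn_snps\th2_random_mean\tp_kd\n")
            for t_i, trait in enumerate(sorted(config.traits)):
                gwas = gwas_by_trait[trait]
                total = set_h2(gwas, ld, gwas.snp_ids, config.n, label="total")
                fh.write(
                    f"{trait}\ttotal\t{total.h2:.6g}\t{total.se:.6g}\t{total.n_snps}\t\t\n"
                )
                hits = gwas_hits_h2(gwas, ld, config.n, p_max=config.thr("hits_p_max"))
                fh.write(
                    f"{trait}\tgwas_hits\t{hits.h2:.6g}\t{hits.se:.6g}\t{hits.n_snps}\t\t\n"
                )
                m = combined_by_trait[trait]
                mapped_genes = m.gene_ids
                for n_i, (nname, sub_genes) in enumerate(sorted(kd_subnets.items())):
                    target = sorted(sub_genes & mapped_genes)
                    pool = sorted(mapped_genes - sub_genes)
                    if not target or len(pool) < len(target):
                        continue
                    cmp_res = kd_subnetwork_h2_test(
                        gwas,
                        ld,
                        m,
                        target,
                        pool,
                        config.n,
                        n_perm=config.perms("h2"),
                        seed=_sub_seed(config.seed, 4, t_i, n_i),
                        r2_max=config.thr("r2_max"),
                    )
                    fh.write(
                        f"{trait}\tkd_subnetwork_{nname}\t{cmp_res.h2_target:.6g}\t\t\t"
                        f"{cmp_res.h2_random_mean:.6g}\t{cmp_res.p_kd_display()}\n"
                    )

        stage = "manifest"
        outputs = sorted(
            f for f in os.listdir(out) if f != "manifest.json" and not f.startswith(".")
        )
        cfg_repr = json.dumps(
            {
                "thresholds": {k: config.thr(k) for k in _DEFAULT_THRESHOLDS},
                "n_perm": {k: config.perms(k) for k in _DEFAULT_N_PERM},
                "seed": config.seed,
                "n": config.n,
                "traits": sorted(config.traits),
                "networks": sorted(config.networks),
            },
            sort_keys=True,
        )
        manifest = {
            "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest(),
            "seed": config.seed,
            "version": _package_version(),
            "outputs": {f: _sha256(os.path.join(out, f)) for f in outputs},
        }
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return out
    except Exception as exc:
        marker = os.path.join(out, "FAILED")
        with open(marker, "w") as fh:
            fh.write(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("gwasnet")
    except PackageNotFoundError:
        return "unknown"
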