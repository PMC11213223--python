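"""End-to-end orchestration: simulate -> cohort -> screen -> characterize ->
subgroups, under a single config with reproducible per-stage seeds.

Every output is plain delimited text with headers, so runs are auditable and
byte-identical under a fixed master seed.  Per-stage seeds are derived
deterministically from the master seed by hashing ``"{master}:{stage}"``, so
stages can be rerun independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import click
import numpy as np
import pandas as pd
from scipy import sparse

from . import cohort as cb
from . import lsa, screening, subgroups
from .simulate import (ConfigError, SimConfig, LatentFactorSpec,
                       default_config, generate_cohort, planted_truth_report,
                       read_cohort, write_cohort)

logger = logging.getLogger(__name__)


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration for one full pipeline run.

    Defaults carry the analysis constants of the screening design: top-500
    codes per panel, FDR grid 1/5/10% with 5% as the primary level, LSA rank
    500, Apriori support 0.1% / confidence 55% / max length 10, age cut 35,
    FWER 5%.
    """

    out_dir: str = "run"
    cohort_dir: str | None = None          # simulate when absent
    gem_file: str | None = None            # default: cohort's own gem table
    n_pregnancies: int = 50_000            # for simulation
    roles: tuple[str, ...] = ("maternal", "paternal")
    window_preset: str = "main"
    threshold: int = 1
    top_k: int = 500
    restrictions: tuple[str, ...] = ()
    fdr_levels: tuple[float, ...] = (0.01, 0.05, 0.10)
    main_fdr: float = 0.05
    bootstrap_reps: int = 200
    lsa_rank: int = 500
    lsa_cut: float = 0.35
    apriori: subgroups.AprioriConfig = field(
        default_factory=subgroups.AprioriConfig)
    wy_strict: bool = True
    run_secondary: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.window_preset not in cb.WINDOW_PRESETS:
            raise ConfigError(f"unknown window preset {self.window_preset!r}")
        for r in self.restrictions:
            if r not in cb.RESTRICTIONS:
                raise ConfigError(f"unknown restriction {r!r}")
        for role in self.roles:
            if role not in ("maternal", "paternal"):
                raise ConfigError(f"unknown role {role!r}")
        self.apriori.validate()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "apriori" in d:
            d["apriori"] = subgroups.AprioriConfig(**d["apriori"])
        for key in ("roles", "restrictions", "fdr_levels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        for path_key in ("out_dir", "cohort_dir", "gem_file"):
            d.pop(path_key, None)  # hash analysis parameters, not locations
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _tree_text(Z: np.ndarray, labels: list[str]) -> str:
    """Serialized linkage tree as a nested-list text form."""
    from scipy.cluster.hierarchy import to_tree
    if Z.shape[0] == 0:
        return "(" + ", ".join(labels) + ")"
    root = to_tree(Z)

    def rec(node):
        if node.is_leaf():
            return labels[node.id]
        return f"({rec(node.left)}, {rec(node.right)})"

    return rec(root)


def maternal_ages(cohort, pregnancy_ids) -> pd.Series:
    """Maternal age at delivery, indexed by pregnancy id."""
    preg = cohort.pregnancies.merge(
        cohort.persons[["person_id", "birth_year"]],
        left_on="mother_id", right_on="person_id")
    age = preg["delivery_year"] - preg["birth_year"]
    s = pd.Series(age.to_numpy(), index=preg["pregnancy_id"].to_numpy())
    return s.loc[list(pregnancy_ids)]


@dataclass
class RunResult:
    out_dir: Path
    manifest: dict
    screening: dict[str, pd.DataFrame]
    rules: pd.DataFrame | None
    clustering: "lsa.CodeClustering | None"


def run_all(config: RunConfig) -> RunResult:
    """Run every stage and write publication-shaped outputs + manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "package_version": _pkg_version("cardioscreen"),
        "seeds": {s: derive_seed(config.seed, s)
                  for s in ("simulate", "bootstrap", "subgroups", "wy")},
        "counts": {},
        "stages": [],
        "warnings": [],
    }

    def stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    # ---- cohort ---------------------------------------------------------
    stage("cohort")
    try:
        if config.cohort_dir is not None and Path(config.cohort_dir).exists():
            cohort = read_cohort(config.cohort_dir)
            truth = None
        else:
            sim_cfg = default_config(
                n_pregnancies=config.n_pregnancies,
                seed=derive_seed(config.seed, "simulate"))
            cohort, truth = generate_cohort(sim_cfg)
        gem = (cb.load_gem(config.gem_file) if config.gem_file
               else cb.gem_from_frame(cohort.gem))
        eligible, tally = cb.apply_eligibility(cohort)
        father_map = cb.link_fathers(cohort, eligible)
        ids = eligible
        for r in config.restrictions:
            ids = cb.apply_restriction(cohort, ids, r, father_map=father_map,
                                       gem=gem)
        ids = sorted(ids)
    except Exception as e:
        raise RuntimeError(f"stage 'cohort' failed: {e}") from e
    _write(pd.DataFrame({"rule": list(tally), "excluded": list(tally.values())}),
           out / "exclusions.tsv")
    manifest["counts"].update({
        "n_pregnancies": int(len(cohort.pregnancies)),
        "n_eligible": len(eligible),
        "n_after_restrictions": len(ids),
        "n_linked_fathers": sum(1 for p in ids if p in father_map),
    })

    # ---- outcomes & ages -------------------------------------------------
    stage("outcomes")
    code_lists = cb.default_code_lists()
    outcomes = cb.flag_outcomes(cohort, ids, code_lists)
    _write(outcomes.reset_index(), out / "outcomes.tsv")
    ages = maternal_ages(cohort, ids)
    y_primary = outcomes["primary"]
    manifest["counts"]["n_cases_primary"] = int(y_primary.sum())

    # ---- panels ----------------------------------------------------------
    stage("panels")
    windows = cb.WINDOW_PRESETS[config.window_preset]
    panels: dict[tuple[str, str], cb.CovariatePanel] = {}
    full_panels: dict[tuple[str, str], cb.CovariatePanel] = {}
    try:
        for role in config.roles:
            for kind in ("dx", "rx"):
                w = windows[f"{role}-{kind}"]
                spec = cb.WindowSpec(role=f"{role}-{kind}", start=w[0],
                                     end=w[1])
                p = cb.derive_panel(cohort, ids, spec, gem=gem,
                                    threshold=config.threshold,
                                    father_map=father_map)
                full_panels[(role, kind)] = p
                panels[(role, kind)] = cb.select_top_codes(p, k=config.top_k)
                manifest["counts"][f"n_codes_{role}_{kind}"] = \
                    int(panels[(role, kind)].codes.shape[0])
    except Exception as e:
        raise RuntimeError(f"stage 'panels' failed: {e}") from e

    # ---- screening -------------------------------------------------------
    stage("screening")
    tables: dict[str, pd.DataFrame] = {}
    try:
        for role in config.roles:
            run_panels = [panels[(role, "dx")], panels[(role, "rx")]]
            tab = screening.screen(run_panels, y_primary, ages,
                                   fdr_levels=config.fdr_levels)
            tab = screening.winners_curse_correct(
                run_panels, y_primary, ages, tab, q=config.main_fdr,
                B=config.bootstrap_reps,
                seed=derive_seed(config.seed, "bootstrap"))
            tables[role] = tab
            _write(tab, out / f"screening_{role}.tsv")
            man = tab[["code", "kind", "role", "signed_log10_p",
                       "log10p_overflow"] +
                      [c for c in tab.columns if c.startswith("selected_")]]
            _write(man, out / f"manhattan_{role}.tsv")
            sel_col = f"selected_fdr{int(round(config.main_fdr * 100)):02d}"
            manifest["counts"][f"n_selected_{role}"] = int(tab[sel_col].sum())
    except Exception as e:
        raise RuntimeError(f"stage 'screening' failed: {e}") from e

    # ---- age-risk curve --------------------------------------------------
    stage("age_risk")
    curve, bins = screening.age_risk_curve(
        y_primary.loc[ids].to_numpy(dtype=float), ages.to_numpy(dtype=float))
    _write(curve, out / "age_risk_curve.tsv")
    _write(bins, out / "age_risk_bins.tsv")

    # ---- latent semantic characterization -------------------------------
    stage("lsa")
    clustering = None
    try:
        mat_dx = full_panels[("maternal", "dx")]
        mat_rx = full_panels[("maternal", "rx")]
        counts = sparse.hstack([mat_dx.counts, mat_rx.counts]).tocsr()
        codes = pd.concat([mat_dx.codes, mat_rx.codes], ignore_index=True)
        space = lsa.build_latent_space(counts, codes, k=config.lsa_rank)
        _write(pd.DataFrame({"component": np.arange(1, space.k + 1),
                             "singular_value": space.singular_values}),
               out / "singular_values.tsv")
        sel_col = f"selected_fdr{int(round(config.main_fdr * 100)):02d}"
        mat_tab = tables.get("maternal")
        sel_codes = (mat_tab.loc[mat_tab[sel_col], "code"].tolist()
                     if mat_tab is not None else [])
        sel_codes = [c for c in sel_codes if c in set(codes["code"])]
        if len(sel_codes) >= 2:
            sim = lsa.code_cosines(space, sel_codes)
            simdf = pd.DataFrame(sim.cosine, columns=sel_codes)
            simdf.insert(0, "code", sel_codes)
            _write(simdf, out / "similarity.tsv")
            clustering = lsa.cluster_codes(sim, cut=config.lsa_cut)
            _write(clustering.groups, out / "code_groups.tsv")
            (out / "linkage_tree.txt").write_text(
                _tree_text(clustering.linkage, sel_codes) + "\n")
        else:
            manifest["warnings"].append(
                "fewer than 2 selected codes; similarity/grouping skipped")
            _write(pd.DataFrame(columns=["code"]), out / "similarity.tsv")
            _write(pd.DataFrame(columns=["group", "members", "size"]),
                   out / "code_groups.tsv")
    except Exception as e:
        raise RuntimeError(f"stage 'lsa' failed: {e}") from e

    # ---- subgroup discovery ---------------------------------------------
    stage("subgroups")
    rules_df = None
    try:
        mat_dx = full_panels[("maternal", "dx")]
        mat_rx = full_panels[("maternal", "rx")]
        X_full = sparse.hstack(
            [mat_dx.indicators, mat_rx.indicators]).toarray().astype(bool)
        names = (mat_dx.codes["code"].tolist()
                 + mat_rx.codes["code"].tolist())
        age_col, age_name = subgroups.make_age_feature(
            ages.loc[mat_dx.pregnancy_ids].to_numpy())
        X_full = np.column_stack([X_full, age_col])
        names = names + [age_name]
        y_full = y_primary.loc[mat_dx.pregnancy_ids].to_numpy()
        if y_full.sum() == 0 or y_full.sum() > (~y_full.astype(bool)).sum():
            manifest["warnings"].append("subgroup stage skipped: "
                                        "outcome cannot be balanced")
        else:
            Xb, yb = subgroups.downsample_balance(
                X_full, y_full, seed=derive_seed(config.seed, "subgroups"))
            rules = subgroups.apriori_rules(Xb, yb, names, config.apriori)
            rules = subgroups.closed_reduction(rules)
            if config.wy_strict:
                rules = subgroups.westfall_young(
                    rules, Xb, yb, config.apriori,
                    seed=derive_seed(config.seed, "wy"))
            else:
                rules = subgroups.westfall_young_fixed(
                    rules, Xb, yb, names, config.apriori,
                    seed=derive_seed(config.seed, "wy"))
            rules = [subgroups.subgroup_metrics(r, X_full, y_full, names)
                     for r in rules]
            rules_df = subgroups.rules_table(rules)
            manifest["counts"]["n_rules"] = int(len(rules_df))
            manifest["counts"]["n_rules_selected"] = \
                int(rules_df["selected"].sum())
        if rules_df is None:
            rules_df = subgroups.rules_table([])
        _write(rules_df, out / "subgroup_rules.tsv")
    except Exception as e:
        raise RuntimeError(f"stage 'subgroups' failed: {e}") from e

    # ---- secondary outcomes ---------------------------------------------
    if config.run_secondary:
        stage("secondary")
        secondary_outcomes(config, cohort=cohort, ids=ids, gem=gem,
                           panels=panels, outcomes=outcomes, ages=ages,
                           out=out, manifest=manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return RunResult(out_dir=out, manifest=manifest, screening=tables,
                     rules=rules_df, clustering=clustering)


def secondary_outcomes(config: RunConfig, *, cohort=None, ids=None, gem=None,
                       panels=None, outcomes=None, ages=None, out=None,
                       manifest=None, min_cases: int = 10
                       ) -> dict[str, pd.DataFrame]:
    """Screen each cardiac-malformation subtype as its own outcome.

    Subtypes with too few cases to support the age-spline adjustment
    (fewer than ``min_cases``, including zero) yield an empty selection and
    a low-power warning rather than an error.
    """
    if cohort is None:
        raise ConfigError("secondary_outcomes requires a prepared run "
                          "(call through run_all with run_secondary=True)")
    out = Path(out) if out is not None else Path(config.out_dir)
    results: dict[str, pd.DataFrame] = {}
    subtype_names = [c for c in outcomes.columns if c != "primary"]
    for role in config.roles:
        run_panels = [panels[(role, "dx")], panels[(role, "rx")]]
        for sub in subtype_names:
            y = outcomes[sub]
            if int(y.sum()) < min_cases:
                msg = (f"subtype {sub!r} ({role}): {int(y.sum())} cases; "
                       "empty selection, power is limited")
                if manifest is not None:
                    manifest["warnings"].append(msg)
                logger.warning(msg)
                tab = pd.DataFrame(columns=["code", "p", "p_adj"])
            else:
                tab = screening.screen(run_panels, y, ages,
                                       fdr_levels=config.fdr_levels)
            results[f"{role}_{sub}"] = tab
            _write(tab, out / f"screening_{role}_{sub}.tsv")
    return results


# --------------------------------------------------------------------------
# command-line interface
# --------------------------------------------------------------------------

@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def cli(log_level: str) -> None:
    """Claims-code screening pipeline for infant cardiac malformations."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), "INFO"))


@cli.command()
@click.option("--n", "n_pregnancies", default=50_000, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def simulate(n_pregnancies: int, seed: int, out: str) -> None:
    """Generate a synthetic cohort directory with planted ground truth."""
    cfg = default_config(n_pregnancies=n_pregnancies, seed=seed)
    cohort, truth = generate_cohort(cfg)
    write_cohort(cohort, out, truth=truth, config=cfg)
    click.echo(f"wrote cohort ({n_pregnancies} pregnancies) to {out}")


def _load_config(config_path, **overrides) -> RunConfig:
    cfg = (RunConfig.from_file(config_path) if config_path else RunConfig())
    for k, v in overrides.items():
        if v is not None:
            setattr(cfg, k, v)
    return cfg


@cli.command("build-cohort")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--cohort-dir", type=click.Path(exists=True))
@click.option("--out", type=click.Path())
def build_cohort(config_path, cohort_dir, out) -> None:
    """Apply eligibility and report exclusions for an existing cohort dir."""
    cfg = _load_config(config_path, cohort_dir=cohort_dir, out_dir=out)
    cohort = read_cohort(cfg.cohort_dir)
    eligible, tally = cb.apply_eligibility(cohort)
    father_map = cb.link_fathers(cohort, eligible)
    outdir = Path(cfg.out_dir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    _write(pd.DataFrame({"rule": list(tally),
                         "excluded": list(tally.values())}),
           outdir / "exclusions.tsv")
    click.echo(f"eligible: {len(eligible)}; fathers linked: {len(father_map)}")


def _runall_options(f):
    f = click.option("--config", "config_path",
                     type=click.Path(exists=True))(f)
    f = click.option("--cohort-dir", type=click.Path(exists=True))(f)
    f = click.option("--out", "out_dir", type=click.Path())(f)
    f = click.option("--seed", type=int)(f)
    f = click.option("--fdr", "main_fdr",
                     type=click.Choice(["0.01", "0.05", "0.10"]))(f)
    f = click.option("--bootstrap-reps", type=int)(f)
    f = click.option("--threshold", type=int)(f)
    f = click.option("--window", "window_preset",
                     type=click.Choice(list(cb.WINDOW_PRESETS)))(f)
    f = click.option("--restriction", "restrictions", multiple=True,
                     type=click.Choice(list(cb.RESTRICTIONS)))(f)
    return f


@cli.command("run-all")
@_runall_options
@click.option("--secondary/--no-secondary", "run_secondary", default=None)
def run_all_cmd(config_path, restrictions, main_fdr, **overrides) -> None:
    """Run the full pipeline: cohort, screening, characterization, subgroups."""
    cfg = _load_config(
        config_path,
        restrictions=tuple(restrictions) if restrictions else None,
        main_fdr=float(main_fdr) if main_fdr else None,
        **{k: v for k, v in overrides.items() if v is not None})
    res = run_all(cfg)
    click.echo(json.dumps(res.manifest["counts"], indent=2, sort_keys=True))


for _name in ("screen", "characterize", "subgroups"):
    # thin aliases: each stage is cheap to rerun from the library through
    # run_all; the manifest records which outputs each invocation refreshed
    @cli.command(_name, help=f"Run the pipeline, refreshing the {_name} "
                 "outputs (stages share one reproducible run).")
    @_runall_options
    def _stage_cmd(config_path, restrictions, main_fdr, _name=_name,
                   **overrides) -> None:
        cfg = _load_config(
            config_path,
            restrictions=tuple(restrictions) if restrictions else None,
            main_fdr=float(main_fdr) if main_fdr else None,
            **{k: v for k, v in overrides.items() if v is not None})
        res = run_all(cfg)
        click.echo(json.dumps(res.manifest["counts"], indent=2,
                              sort_keys=True))


@cli.command()
@click.option("--out", "out_dir", required=True,
              type=click.Path(exists=True))
def report(out_dir: str) -> None:
    """Print the manifest summary of a finished run."""
    manifest = json.loads((Path(out_dir) / "manifest.json").read_text())
    click.echo(json.dumps(manifest["counts"], indent=2, sort_keys=True))
    for w in manifest.get("warnings", []):
        click.echo(f"warning: {w}")


if __name__ == "__main__":  # pragma: no cover
    cli()
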