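"""End-to-end orchestration: registry -> features -> model -> flags.

``run`` executes prepare -> featurize -> encode -> select -> train/evaluate
-> (optional) compare-feature-sets -> (optional) explain with per-stage
seeds derived from one master seed, persisting machine-readable artifacts
after each stage so any stage can be rerun or audited in isolation. The
:class:`FeaturePipeline` bundles everything needed to featurize new
records with training-time state (imputer, encoder levels, search terms),
which is what makes single-protocol explanation possible after the fact.
"""

from __future__ import annotations

import dataclasses
import json
import time
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from . import categories as cat_mod
from . import eligibility as elig_mod
from . import registry as reg_mod
from .encoding import (
    DesignMatrix,
    EncoderSpec,
    ImputationModel,
    fit_encoder,
    mice_fit_transform,
    mice_transform,
    one_hot,
)
from .model import (
    ClassifierSpec,
    TerminationRiskModel,
    TerminationRiskResults,
    tune_staged,
)
from .selection import (
    SplitIndices,
    ablation_elbow,
    anova_f_scores,
    select_k_best,
    split_train_test,
    undersample,
)
from .synthetic import (
    SyntheticConfig,
    generate_lexicon,
    generate_records,
    generate_term_corpus,
    write_registry_export,
    write_term_corpus,
)

log = logging.getLogger("trialterm")


@dataclass(slots=True)
class PipelineConfig:
    """Structured run configuration; exactly one data source.

    Either the three input paths (registry export, term corpus, lexicon)
    or a ``synthetic`` block must be given, never both.
    """

    registry_path: str | None = None
    corpus_path: str | None = None
    lexicon_path: str | None = None
    synthetic: dict | None = None
    delimiter: str = "|"
    min_year: int = 2011
    split_ratio: float = 0.70
    stratified: bool = True
    undersample_ratio: float = 1.0
    k: int | None = None
    k_grid: list[int] | None = None
    family: str = "gradient_boosting"
    hyperparameters: dict = field(default_factory=lambda: {"max_depth": 4, "n_trees": 200})
    tune: dict | None = None
    cv_folds: int = 5
    compare: bool = False
    explain: bool = False
    flag_threshold: float = 0.5
    top_k: int = 8
    background_size: int = 100
    n_explain: int = 3
    seed: int = 0
    out_dir: str = "trialterm_run"

    def __post_init__(self):
        has_paths = self.registry_path is not None
        has_synth = self.synthetic is not None
        if has_paths == has_synth:
            raise ValueError(
                "config must give exactly one of registry_path or a synthetic block"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def stage_seeds(master: int, n: int = 8) -> list[int]:
    """Derive per-stage seeds from one master seed (splittable, < 2^31)."""
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


class FeaturePipeline:
    """Record featurizer carrying all training-time state.

    fit() learns the imputer, categorical levels, intervention-type and
    category vocabularies from the *training* records only; transform()
    then maps any records — including a single unseen protocol — onto the
    exact training-time column layout.
    """

    def __init__(self, terms, lexicon,
                 numeric=reg_mod.DEFAULT_CHARACTERISTIC_NUMERIC,
                 categorical=reg_mod.DEFAULT_CHARACTERISTIC_CATEGORICAL):
        self.terms = list(terms)
        self.lexicon = lexicon
        self.numeric = list(numeric)
        self.categorical = list(categorical)
        self.category_order = sorted(lexicon.categories)
        self.imputation: ImputationModel | None = None
        self.encoder: EncoderSpec | None = None
        self.itype_levels: list[str] | None = None

    # -- internals ---------------------------------------------------------
    def _tables(self, records: Sequence[reg_mod.TrialRecord]):
        chars = [reg_mod.extract_characteristics(r, self.numeric, self.categorical)
                 for r in records]
        docs = [elig_mod.parse_document(r.registry_id, r.eligibility_text)
                for r in records]
        stats = [elig_mod.criteria_stats(d) for d in docs]
        ids = [r.registry_id for r in records]
        numeric_df = pd.DataFrame(
            {**{f"char:{f}": [c[f] for c in chars] for f in self.numeric},
             **{f"elig:{k}": [s[k] for s in stats]
                for k in ("n_inclusion", "n_exclusion", "total_words",
                          "avg_words_per_criterion")}},
            index=ids, dtype=float,
        )
        cat_df = pd.DataFrame(
            {f: [c[f] for c in chars] for f in self.categorical}, index=ids
        )
        return ids, chars, docs, numeric_df, cat_df

    def fit(self, records: Sequence[reg_mod.TrialRecord],
            train_ids: Sequence[str], seed: int = 0,
            mice_max_iter: int = 30, mice_tol: float = 1e-3) -> "FeaturePipeline":
        ids, chars, _docs, numeric_df, cat_df = self._tables(records)
        train = [i for i in ids if i in set(train_ids)]
        _, self.imputation = mice_fit_transform(
            numeric_df.loc[train], max_iter=mice_max_iter, tol=mice_tol, seed=seed
        )
        self.encoder = fit_encoder(cat_df.loc[train])
        train_set = set(train)
        self.itype_levels = sorted(
            {t for r in records if r.registry_id in train_set
             for t in r.intervention_types}
        )
        return self

    def transform(self, records: Sequence[reg_mod.TrialRecord]):
        """Returns (row_ids, column_names, csr matrix) on the fitted layout."""
        if self.imputation is None:
            raise ValueError("FeaturePipeline must be fit before transform")
        ids, chars, docs, numeric_df, cat_df = self._tables(records)
        numeric_done = mice_transform(numeric_df, self.imputation)
        onehot, _ = one_hot(cat_df, self.encoder)

        itype = np.zeros((len(records), len(self.itype_levels)), dtype=np.int8)
        for i, r in enumerate(records):
            for t in r.intervention_types:
                if t in self.itype_levels:
                    itype[i, self.itype_levels.index(t)] = 1
        phase = np.array(
            [[int(p in r.phases) for p in reg_mod.PHASES] for r in records],
            dtype=np.int8,
        )
        assignments = [cat_mod.assign_categories(r, self.lexicon) for r in records]
        cat_block = cat_mod.encode_category_features(assignments, self.category_order)
        term_matrix = elig_mod.match_terms(docs, self.terms)

        names = (
            list(numeric_done.columns)
            + [f"char:{c}" for c in self.encoder.column_names]
            + [f"char:intervention_type={t}" for t in self.itype_levels]
            + [f"char:phase_{p}" for p in reg_mod.PHASES]
            + [f"cat:{c}" for c in self.category_order]
            + [f"term:{t.name}" for t in self.terms]
        )
        X = sparse.hstack(
            [
                sparse.csr_matrix(numeric_done.to_numpy(dtype=float)),
                onehot,
                sparse.csr_matrix(itype),
                sparse.csr_matrix(phase),
                sparse.csr_matrix(cat_block),
                term_matrix.matrix,
            ],
            format="csr",
        ).astype(float)
        return ids, names, X

    # -- persistence -------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "numeric": self.numeric,
            "categorical": self.categorical,
            "category_order": self.category_order,
            "itype_levels": self.itype_levels,
            "lexicon": {c: sorted(" ".join(t) for t in ts)
                        for c, ts in self.lexicon.categories.items()},
            "terms": [{"term_id": t.term_id, "side": t.side,
                       "category": t.category, "value": " ".join(t.value)}
                      for t in self.terms],
            "encoder": {"levels": self.encoder.levels,
                        "column_names": self.encoder.column_names},
            "imputation": {
                k: getattr(self.imputation, k)
                for k in ("feature_order", "visit_order", "coefficients",
                          "intercepts", "init_values", "n_iterations",
                          "converged", "tolerance", "alpha", "seed")
            } | {"clamp_bounds": self.imputation.clamp_bounds},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FeaturePipeline":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        terms = [elig_mod.SearchTerm(term_id=t["term_id"], side=t["side"],
                                     category=t["category"],
                                     value=tuple(t["value"].split()))
                 for t in d["terms"]]
        lexicon = cat_mod.CategoryLexicon.from_mapping(d["lexicon"])
        fp = cls(terms, lexicon, numeric=d["numeric"], categorical=d["categorical"])
        fp.category_order = d["category_order"]
        fp.itype_levels = d["itype_levels"]
        fp.encoder = EncoderSpec(levels=d["encoder"]["levels"],
                                 column_names=d["encoder"]["column_names"])
        imp = dict(d["imputation"])
        if imp["clamp_bounds"] is not None:
            imp["clamp_bounds"] = {k: tuple(v) for k, v in imp["clamp_bounds"].items()}
        fp.imputation = ImputationModel(**imp)
        return fp


@dataclass(slots=True)
class RunReport:
    """Machine-readable account of one pipeline run."""

    config: dict
    seeds: dict
    counts: dict
    feature_counts: dict
    selected_k: int | None
    cv_metrics: dict | None
    test_metrics: dict | None
    mcnemar: dict | None
    flags: list[dict]
    artifacts: dict
    version: str

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


_STAGES = ("simulate", "prepare", "featurize", "select", "train", "compare", "explain")


def run(config: PipelineConfig, stop_after: str | None = None) -> RunReport:
    """Execute the pipeline; artifacts land in ``config.out_dir``.

    ``stop_after`` truncates the run at a named stage ("prepare",
    "featurize", ...). Rerunning with the same config and seed reproduces
    every report byte for byte.
    """
    from . import __version__

    if stop_after is not None and stop_after not in _STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(
        ("simulate", "split", "undersample", "cv", "model", "background",
         "tune", "spare"),
        stage_seeds(config.seed),
    ))
    report = RunReport(
        config=dataclasses.asdict(config), seeds=seeds, counts={},
        feature_counts={}, selected_k=None, cv_metrics=None,
        test_metrics=None, mcnemar=None, flags=[], artifacts={},
        version=__version__,
    )

    def _stage_done(name: str) -> bool:
        report.to_json(out / "run_report.json")
        return stop_after == name

    t0 = time.time()

    # -- simulate / load ---------------------------------------------------
    if config.synthetic is not None:
        synth = SyntheticConfig(**{**config.synthetic, "seed": seeds["simulate"]})
        corpus_rows, _planted = generate_term_corpus(synth)
        lexicon = generate_lexicon(synth)
        records, labels, truth = generate_records(synth, corpus_rows, lexicon)
        registry_path = out / "registry_export.psv"
        write_registry_export(records, registry_path, delimiter=config.delimiter)
        write_term_corpus(corpus_rows, out / "term_corpus.csv")
        lexicon.to_json(out / "lexicon.json")
        with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(truth), fh)
        report.artifacts["registry_export"] = str(registry_path)
        records = reg_mod.read_registry_table(registry_path, config.delimiter)
    else:
        records = reg_mod.read_registry_table(config.registry_path, config.delimiter)
        corpus_rows = elig_mod.read_term_corpus(config.corpus_path)
        lexicon = (cat_mod.CategoryLexicon.from_json(config.lexicon_path)
                   if config.lexicon_path else cat_mod.default_lexicon())
    report.counts["raw_records"] = len(records)
    log.info("loaded %d records (%.1fs)", len(records), time.time() - t0)
    if _stage_done("simulate"):
        return report

    # -- prepare -----------------------------------------------------------
    filtered = reg_mod.filter_records(records, min_year=config.min_year)
    labels = {r.registry_id: reg_mod.assign_label(r).label for r in filtered}
    report.counts["filtered_records"] = len(filtered)
    report.counts["class_failure"] = int(sum(1 for v in labels.values() if v == 0))
    report.counts["class_success"] = int(sum(1 for v in labels.values() if v == 1))
    rates = reg_mod.missing_rate_by_year(records)
    with open(out / "missing_rates.json", "w", encoding="utf-8") as fh:
        json.dump({str(y): r for y, r in rates.items()}, fh, indent=1)
    report.artifacts["missing_rates"] = str(out / "missing_rates.json")
    if _stage_done("prepare"):
        return report

    # -- featurize + encode ------------------------------------------------
    terms = elig_mod.build_search_terms(corpus_rows)
    split = split_train_test(
        [r.registry_id for r in filtered],
        [labels[r.registry_id] for r in filtered],
        ratio=config.split_ratio, seed=seeds["split"],
        stratified=config.stratified,
    )
    fp = FeaturePipeline(terms, lexicon).fit(filtered, split.train_ids,
                                             seed=seeds["model"])
    ids, names, X = fp.transform(filtered)
    # transform() already namespaces columns, so the design is direct
    design = DesignMatrix(ids, names, X, np.array([labels[i] for i in ids], dtype=int))
    fp.to_json(out / "feature_pipeline.json")
    elig_mod.write_search_terms(terms, out / "search_terms.csv")
    report.artifacts["feature_pipeline"] = str(out / "feature_pipeline.json")
    report.feature_counts = {
        "total": len(design.column_names),
        "search_terms": len(terms),
        "categories": len(fp.category_order),
    }
    if _stage_done("featurize"):
        return report

    # -- select ------------------------------------------------------------
    train_design = design.subset_rows(split.train_ids)
    balanced_ids = undersample(train_design.row_ids,
                               dict(zip(design.row_ids, design.y)),
                               ratio=config.undersample_ratio,
                               seed=seeds["undersample"])
    balanced = design.subset_rows(balanced_ids)
    ranking = anova_f_scores(balanced.X, balanced.y, design.column_names)
    selected_k = config.k
    if config.k_grid:
        def eval_k(k: int) -> float:
            cols = select_k_best(ranking, k)
            sub = TerminationRiskModel(
                design.subset_columns(cols),
                spec=ClassifierSpec(config.family, config.hyperparameters,
                                    seeds["model"]),
                split=split, undersample_ratio=config.undersample_ratio,
                seed=seeds["undersample"],
            ).fit(cv_folds=2)
            return 1.0 - sub.test_report.balanced_accuracy

        grid = [k for k in config.k_grid if k <= ranking.n_defined]
        curve = ablation_elbow(grid, eval_k)
        pd.DataFrame({"k": curve.k_grid, "error": curve.error_at_k}).to_csv(
            out / "ablation.csv", index=False
        )
        selected_k = curve.elbow_k
    if selected_k is None:
        selected_k = ranking.n_defined
    selected = select_k_best(ranking, min(selected_k, ranking.n_defined))
    with open(out / "selected_features.json", "w", encoding="utf-8") as fh:
        json.dump(selected, fh)
    report.selected_k = int(selected_k)
    if _stage_done("select"):
        return report

    # -- train / evaluate --------------------------------------------------
    spec = ClassifierSpec(config.family, dict(config.hyperparameters), seeds["model"])
    if config.tune:
        spec = tune_staged(
            config.family, balanced.subset_columns(selected).X, balanced.y,
            config.tune.get("stage1", {}), config.tune.get("stage2", {}),
            seed=seeds["tune"], base_hyperparameters=config.hyperparameters,
        )
    model = TerminationRiskModel(
        design.subset_columns(selected), spec=spec, split=split,
        undersample_ratio=config.undersample_ratio, seed=seeds["undersample"],
    )
    results = model.fit(cv_folds=config.cv_folds)
    report.cv_metrics = results.cv_report.as_dict()
    report.test_metrics = results.test_report.as_dict()
    if hasattr(results.classifier, "get_booster"):
        results.classifier.get_booster().save_model(str(out / "model.json"))
        report.artifacts["model"] = str(out / "model.json")
    log.info("trained %s (%.1fs)", spec.family, time.time() - t0)
    if _stage_done("train"):
        return report

    # -- compare feature sets ---------------------------------------------
    if config.compare:
        char_cols = [c for c in design.column_names
                     if c.startswith(("char:", "elig:"))]
        base_model = TerminationRiskModel(
            design.subset_columns(char_cols), spec=spec, split=split,
            undersample_ratio=config.undersample_ratio, seed=seeds["undersample"],
        )
        base_results = base_model.fit(cv_folds=config.cv_folds)
        comparison = results.compare(base_results)
        report.mcnemar = comparison.as_dict() | {
            "augmented_test": results.test_report.as_dict(),
            "characteristics_only_test": base_results.test_report.as_dict(),
        }
    if _stage_done("compare"):
        return report

    # -- explain -----------------------------------------------------------
    if config.explain:
        test = design.subset_columns(selected).subset_rows(split.test_ids)
        probs = results.predict_proba(test.X)
        order = np.argsort(probs)[: config.n_explain]
        for i in order:
            x = np.asarray(test.X[int(i)].todense()).ravel()
            flag = results.flag(
                x, threshold=config.flag_threshold, top_k=config.top_k,
                background_size=config.background_size,
                registry_id=test.row_ids[int(i)],
            )
            report.flags.append(flag.as_dict())
        with open(out / "flags.json", "w", encoding="utf-8") as fh:
            json.dump(report.flags, fh, indent=1)
    report.to_json(out / "run_report.json")
    return report


def explain_one(artifact_dir, record_path, threshold: float = 0.5,
                top_k: int = 8, delimiter: str = "|",
                background: np.ndarray | None = None):
    """Featurize one new protocol with training-time state and flag it.

    ``artifact_dir`` must hold ``feature_pipeline.json``, ``model.json``
    and ``selected_features.json`` from a previous run.
    """
    import xgboost as xgb

    from .interpret import flag_protocol

    artifact_dir = Path(artifact_dir)
    fp = FeaturePipeline.from_json(artifact_dir / "feature_pipeline.json")
    with open(artifact_dir / "selected_features.json", encoding="utf-8") as fh:
        selected = json.load(fh)
    clf = xgb.Booster()
    clf.load_model(str(artifact_dir / "model.json"))
    records = reg_mod.read_registry_table(record_path, delimiter)
    if len(records) != 1:
        raise ValueError(f"expected exactly one record, found {len(records)}")
    ids, names, X = fp.transform(records)
    index = {c: j for j, c in enumerate(names)}
    missing = [c for c in selected if c not in index]
    if missing:
        raise ValueError(f"schema drift: trained features absent: {missing[:5]}")
    x = np.asarray(X[:, [index[c] for c in selected]].todense()).ravel()
    if background is None:
        background = np.zeros((1, len(selected)))
    return flag_protocol(clf, x, threshold, top_k=top_k,
                         background_sample=background,
                         feature_names=selected, registry_id=ids[0])
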