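"""Recovery experiments on simulated cohorts.

These are the package's standing validation experiments: each one
builds synthetic data with a known ground truth, runs the regular
analysis chain, and reports how well the truth is recovered.  They are
used by the test suite and the reproduction script; problem sizes are
chosen for a desk-scale single-CPU run (60-s recordings for the cohort
experiments, 300-s signals for the volume-conduction check).
"""

from __future__ import annotations

import warnings

import numpy as np

from oscillome.bands import get_band
from oscillome.cpm import CPMClassifier
from oscillome.pec import (
    orthogonalized_envelope_correlation,
    pec_matrix,
    vectorize_pec,
    znorm_features,
)
from oscillome.spectral import band_envelope_coefficients, band_power, welch_psd, znorm_psd
from oscillome.stats import RobustnessConfig, compare_groups
from oscillome.synth import EffectSpec, SynthCohortConfig, gen_subject


def volume_conduction_suppression(
    n_seeds: int = 20,
    duration: float = 300.0,
    fs: float = 500.0,
    band_name: str = "alpha",
    seed: int = 0,
) -> dict:
    """PEC vs plain envelope correlation for mixtures of a single source.

    Two sensors receive instantaneous mixtures (random weights, random
    signs) of one simulated source.  Orthogonalized PEC should stay
    near zero while the plain log-envelope correlation is ~1 — the
    zero-phase-lag suppression property.
    """
    band = get_band(band_name)
    root = np.random.SeedSequence(seed)
    pecs, plains = [], []
    for child in root.spawn(n_seeds):
        rng = np.random.default_rng(child)
        cfg = SynthCohortConfig(
            n_per_group={"HC": 2},
            duration=duration,
            fs=fs,
            n_regions=1,
            seed=int(rng.integers(2**31)),
        )
        src = gen_subject(cfg, "HC", child).data[0]
        w = rng.uniform(0.3, 1.5, 2) * rng.choice([-1.0, 1.0], 2)
        mix = np.vstack([w[0] * src, w[1] * src])
        coeffs = band_envelope_coefficients(mix, band, fs=fs)
        pecs.append(
            orthogonalized_envelope_correlation(
                coeffs[0], coeffs[1], env_samples_per_point=125
            )
        )
        lp = np.log(np.abs(coeffs) ** 2 + 1e-12)
        plains.append(np.corrcoef(lp[0], lp[1])[0, 1])
    return {
        "pec": np.asarray(pecs),
        "plain": np.asarray(plains),
        "max_abs_pec": float(np.abs(pecs).max()),
        "min_plain_corr": float(np.min(plains)),
    }


def planted_power_recovery(
    n_seeds: int = 10,
    n_per_group: int = 30,
    n_regions: int = 113,
    n_targets: int = 10,
    effect_d: float = 1.2,
    band_name: str = "theta",
    duration: float = 60.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Sensitivity / false-discovery proportion of the full stats stack.

    A band-power elevation (Cohen's d ``effect_d``) is planted in
    ``n_targets`` regions of the patient group; recovery runs the
    complete inference chain (t-test, label permutations, BH-FDR, and
    the 100x95% subsample-robustness screen) on the z-normalized
    band-power features and scores the FDR-significant set against the
    planted truth, averaged over seeds.
    """
    from oscillome.bands import DEFAULT_BANDS

    band_idx = [b.name for b in DEFAULT_BANDS].index(band_name)
    root = np.random.SeedSequence(seed)
    sens, fdps, robust_sens = [], [], []
    for child in root.spawn(n_seeds):
        cfg = SynthCohortConfig(
            n_per_group={"HC": n_per_group, "PKD": n_per_group},
            duration=duration,
            n_regions=n_regions,
            seed=0,
        )
        targets = tuple(cfg.region_names[:n_targets])
        cfg.effects = (EffectSpec("band_power", band_name, targets, effect_d, "PKD"),)
        subject_seeds = child.spawn(2 * n_per_group + 1)
        feats, labels = [], []
        for i in range(2 * n_per_group):
            group = "HC" if i < n_per_group else "PKD"
            sub = gen_subject(cfg, group, subject_seeds[i])
            feats.append(band_power(znorm_psd(welch_psd(sub)))[:, band_idx])
            labels.append(group)
        X = np.asarray(feats)
        labels = np.asarray(labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = compare_groups(
                X,
                labels,
                n_perm=n_perm,
                robustness=RobustnessConfig(),
                seed=int(np.random.default_rng(subject_seeds[-1]).integers(2**31)),
            )
        truth = np.zeros(n_regions, dtype=bool)
        truth[:n_targets] = True
        sig = comp.significant
        sens.append((sig & truth).sum() / n_targets)
        fdps.append((sig & ~truth).sum() / max(int(sig.sum()), 1))
        robust_sens.append((comp.robust & truth).sum() / n_targets)
    return {
        "sensitivity": float(np.mean(sens)),
        "fdp": float(np.mean(fdps)),
        "robust_sensitivity": float(np.mean(robust_sens)),
        "per_seed_sensitivity": np.asarray(sens),
        "per_seed_fdp": np.asarray(fdps),
    }


def _coupling_cohort_features(cfg, band, n_per_group, groups, seed_seq):
    """High-gamma PEC feature matrix for one simulated cohort (streamed)."""
    children = seed_seq.spawn(2 * n_per_group)
    X, y = [], []
    for i in range(2 * n_per_group):
        group = groups[0] if i < n_per_group else groups[1]
        sub = gen_subject(cfg, group, children[i])
        coeffs = band_envelope_coefficients(sub, band)
        mat = pec_matrix(coeffs, env_samples_per_point=4, subsample=10)
        X.append(vectorize_pec(mat, include_diagonal=False))
        y.append(0 if i < n_per_group else 1)
    return np.asarray(X), np.asarray(y)


def cpm_coupling_recovery(
    n_seeds: int = 10,
    n_per_group: int = 25,
    n_regions: int = 30,
    n_pairs: int = 20,
    coupling_delta: float = -0.4,
    duration: float = 60.0,
    n_label_perms_per_seed: int = 2,
    p_threshold: float = 0.3,
    seed: int = 0,
) -> dict:
    """Train/external CPM performance on a planted coupling deficit.

    The non-remission group's high-gamma envelope coupling is lowered
    by ``coupling_delta`` on ``n_pairs`` region pairs.  Per seed, a
    training and an independent external cohort are simulated; the CPM
    is fitted on the training cohort's z-scored PEC features and
    applied unchanged to the external cohort.  The label-permutation
    null refits on shuffled training labels and evaluates on the
    intact external cohort.
    """
    band = get_band("high_gamma")
    root = np.random.SeedSequence(seed)
    groups = ("remission", "nonremission")
    train_aucs, ext_aucs, perm_aucs, sign_fracs = [], [], [], []
    for child in root.spawn(n_seeds):
        pair_rng = np.random.default_rng(child)
        cfg = SynthCohortConfig(
            n_per_group={g: n_per_group for g in groups},
            duration=duration,
            n_regions=n_regions,
            seed=0,
        )
        used, pairs = set(), []
        while len(pairs) < n_pairs:
            i, j = pair_rng.integers(0, n_regions, 2)
            if i != j and (min(i, j), max(i, j)) not in used:
                used.add((min(i, j), max(i, j)))
                pairs.append((cfg.region_names[i], cfg.region_names[j]))
        cfg.effects = (
            EffectSpec("envelope_coupling", "high_gamma", tuple(pairs), coupling_delta, groups[1]),
        )
        tr_seq, ex_seq = child.spawn(2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xtr, ytr = _coupling_cohort_features(cfg, band, n_per_group, groups, tr_seq)
            Xex, yex = _coupling_cohort_features(cfg, band, n_per_group, groups, ex_seq)
            Ztr, Zex = znorm_features(Xtr), znorm_features(Xex)
            model = CPMClassifier(p_threshold=p_threshold).fit(Ztr, ytr)
            ext = model.evaluate_external(Zex, yex)
            perm_rng = np.random.default_rng(pair_rng.integers(2**31))
            for _ in range(n_label_perms_per_seed):
                null = CPMClassifier(p_threshold=p_threshold).fit(
                    Ztr, perm_rng.permutation(ytr)
                )
                perm_aucs.append(null.evaluate_external(Zex, yex).auc)
        train_aucs.append(model.train_auc_)
        ext_aucs.append(ext.auc)
        # sign check: group-mean PEC difference on the planted pairs
        name_to_idx = {nm: k for k, nm in enumerate(cfg.region_names)}
        iu = np.triu_indices(n_regions, k=1)
        col_of = {(i, j): k for k, (i, j) in enumerate(zip(*iu))}
        cols = [
            col_of[tuple(sorted((name_to_idx[a], name_to_idx[b])))] for a, b in pairs
        ]
        diff = Xtr[ytr == 1][:, cols].mean(axis=0) - Xtr[ytr == 0][:, cols].mean(axis=0)
        sign_fracs.append(float((diff < 0).mean()))
    return {
        "train_auc": float(np.mean(train_aucs)),
        "external_auc": float(np.mean(ext_aucs)),
        "label_perm_auc": float(np.mean(perm_aucs)),
        "target_pair_negative_fraction": float(np.mean(sign_fracs)),
        "per_seed_train_auc": np.asarray(train_aucs),
        "per_seed_external_auc": np.asarray(ext_aucs),
    }
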