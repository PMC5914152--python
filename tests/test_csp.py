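import numpy as np
import pytest
from scipy import linalg

from fbcsp import extract_trials, fit_csp, select_pairs, transform
from fbcsp.csp import CSPModel
from fbcsp.io import EVENT_RELATED, PRE_EVENT


def toy_trials(var_a=(4.0, 1.0), var_b=(1.0, 4.0), m=64, k=3):
    """Two-channel trials with EXACT diagonal covariances.

    Sampled sin/cos over full periods are exactly orthogonal, so the trial
    covariance X X^T is diagonal with entries var * m/2.
    """
    t = np.arange(m)
    c = np.cos(2 * np.pi * k * t / m)
    s = np.sin(2 * np.pi * k * t / m)
    a = np.stack([np.sqrt(var_a[0]) * c, np.sqrt(var_a[1]) * s])
    b = np.stack([np.sqrt(var_b[0]) * c, np.sqrt(var_b[1]) * s])
    return np.stack([a, a]), np.stack([b, b])


def oracle_csp(trials_a, trials_b):
    """Independent dense eigensolver: explicit loops, whiten-then-eigh."""
    def mean_cov(trials):
        acc = np.zeros((trials.shape[1], trials.shape[1]))
        for x in trials:
            c = x @ x.T
            acc += c / np.trace(c)
        return acc / len(trials)

    c1, c2 = mean_cov(trials_a), mean_cov(trials_b)
    comp = c1 + c2
    white = linalg.inv(linalg.sqrtm(comp).real)
    evals, evecs = np.linalg.eigh(white @ c1 @ white)
    order = np.argsort(evals)[::-1]
    return evals[order], white @ evecs[:, order]


class TestFitCSP:
    def test_identical_classes_give_half_eigenvalues(self, rng):
        trials = rng.standard_normal((10, 3, 100))
        model = fit_csp(trials, trials.copy())
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-10)

    def test_two_channel_toy_exact_eigenvalues(self):
        a, b = toy_trials()
        model = fit_csp(a, b)
        np.testing.assert_allclose(model.eigenvalues, [0.8, 0.2], atol=1e-10)
        # filters along the coordinate axes
        w = model.filters / np.abs(model.filters).max(axis=0)
        assert abs(w[0, 0]) > 0.999 and abs(w[1, 0]) < 1e-6
        assert abs(w[1, 1]) > 0.999 and abs(w[0, 1]) < 1e-6

    def test_matches_brute_force_oracle_on_random_problems(self, rng):
        for _ in range(5):
            a = rng.standard_normal((12, 4, 200)) * rng.uniform(0.5, 2, (1, 4, 1))
            b = rng.standard_normal((12, 4, 200)) * rng.uniform(0.5, 2, (1, 4, 1))
            model = fit_csp(a, b)
            evals, evecs = oracle_csp(a, b)
            np.testing.assert_allclose(model.eigenvalues, evals, atol=1e-8)
            for i in range(4):
                u = model.filters[:, i] / np.linalg.norm(model.filters[:, i])
                v = evecs[:, i] / np.linalg.norm(evecs[:, i])
                assert abs(abs(u @ v) - 1.0) < 1e-6

    def test_matches_mne_csp_filters(self, rng):
        """Independent cross-check against mne's CSP implementation."""
        mne_decoding = pytest.importorskip("mne.decoding")
        a = rng.standard_normal((30, 6, 200)) * np.r_[3, 1, 1, 1, 1, 1][None, :, None]
        b = rng.standard_normal((30, 6, 200)) * np.r_[1, 1, 1, 1, 1, 3][None, :, None]
        ours = fit_csp(a, b)
        mne_csp = mne_decoding.CSP(n_components=6, cov_est="epoch",
                                   norm_trace=True, transform_into="csp_space")
        mne_csp.fit(np.concatenate([a, b]),
                    np.r_[np.zeros(len(a)), np.ones(len(b))])
        theirs = mne_csp.filters_ / np.linalg.norm(mne_csp.filters_, axis=1,
                                                   keepdims=True)
        for i in range(6):
            w = ours.filters[:, i] / np.linalg.norm(ours.filters[:, i])
            assert np.abs(theirs @ w).max() > 0.99

    def test_whitening_and_complement_invariants(self, rng):
        a = rng.standard_normal((15, 5, 150))
        b = rng.standard_normal((15, 5, 150)) * 1.5
        model = fit_csp(a, b)
        swapped = fit_csp(b, a)
        # lambda_i(C1) + lambda_i(C2) = 1 along each eigendirection
        np.testing.assert_allclose(
            np.sort(model.eigenvalues) + np.sort(swapped.eigenvalues)[::-1],
            1.0, atol=1e-8)
        assert np.all(model.eigenvalues >= 0) and np.all(model.eigenvalues <= 1)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        # W whitens the composite covariance: W^T (C1 + C2) W = I
        def mean_cov(trials):
            covs = np.einsum("tcm,tdm->tcd", trials, trials)
            return (covs / np.trace(covs, axis1=1, axis2=2)[:, None, None]).mean(0)
        comp = mean_cov(a) + mean_cov(b)
        np.testing.assert_allclose(model.filters.T @ comp @ model.filters,
                                   np.eye(5), atol=1e-8)

    def test_recovers_ground_truth_unmixing(self, effect_session):
        """The extreme filter aligns with the effect source's unmixing row.

        Broadband epochs: every other source provides full-rank
        interference, so the variance-ratio-extreme filter must null all of
        them, which is exactly the ground-truth unmixing direction.
        """
        rec, events, truth = effect_session
        trials = extract_trials(rec, events)
        model = fit_csp(trials.data[trials.labels == PRE_EVENT],
                        trials.data[trials.labels == EVENT_RELATED])
        u = truth.unmixing_direction(0)
        u = u / np.linalg.norm(u)
        # post-cue variance is amplified, and class a = pre-event, so the
        # effect direction sits at the minimum-eigenvalue end
        w = model.filters[:, -1] / np.linalg.norm(model.filters[:, -1])
        assert abs(w @ u) >= 0.9

    def test_too_few_trials_rejected(self, rng):
        x = rng.standard_normal((1, 3, 50))
        with pytest.raises(ValueError, match="trials"):
            fit_csp(x, x)

    def test_rank_deficient_composite_rejected(self):
        # two perfectly correlated channels -> singular composite covariance
        base = np.random.default_rng(0).standard_normal((4, 1, 100))
        x = np.concatenate([base, base], axis=1)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            fit_csp(x, x * 2.0)


class TestSelectPairs:
    @pytest.fixture
    def model14(self, rng):
        a = rng.standard_normal((20, 14, 100))
        b = rng.standard_normal((20, 14, 100)) * rng.uniform(0.5, 2, (1, 14, 1))
        return fit_csp(a, b)

    def test_three_pairs_from_both_ends(self, model14):
        sel = select_pairs(model14, 3)
        assert sel.selected_indices == (0, 1, 2, 11, 12, 13)
        assert sel.n_components == 6

    def test_zero_pairs_falls_back_to_all(self, model14):
        sel = select_pairs(select_pairs(model14, 3), 0)
        assert sel.selected_indices is None
        assert sel.n_components == 14

    def test_boundary_takes_everything(self, model14):
        sel = select_pairs(model14, 7)
        assert sel.selected_indices == tuple(range(14))

    def test_too_many_pairs_rejected(self, model14):
        with pytest.raises(ValueError):
            select_pairs(model14, 8)


class TestTransform:
    def test_identity_projection(self, rng):
        model = CSPModel(filters=np.eye(3), eigenvalues=np.full(3, 0.5))
        x = rng.standard_normal((3, 40))
        np.testing.assert_allclose(transform(model, x), x)

    def test_linearity(self, rng):
        a = rng.standard_normal((8, 4, 60))
        model = fit_csp(a, rng.standard_normal((8, 4, 60)))
        x = rng.standard_normal((4, 60))
        np.testing.assert_allclose(transform(model, 3.5 * x),
                                   3.5 * transform(model, x), atol=1e-10)

    def test_variance_ordering_on_training_classes(self):
        a, b = toy_trials()
        model = fit_csp(a, b)
        va = transform(model, a).var(axis=-1).mean(axis=0)
        vb = transform(model, b).var(axis=-1).mean(axis=0)
        assert va[0] > vb[0]   # top filter: class-a variance maximized
        assert va[-1] < vb[-1]  # bottom filter: the reverse

    def test_shape_mismatch_rejected(self, rng):
        model = CSPModel(filters=np.eye(3), eigenvalues=np.full(3, 0.5))
        with pytest.raises(ValueError, match="channels"):
            transform(model, rng.standard_normal((4, 10)))


class TestSerialization:
    def test_json_roundtrip(self, rng, tmp_path):
        a = rng.standard_normal((6, 4, 80))
        model = select_pairs(fit_csp(a, a * 2, band_name="alpha"), 1)
        path = tmp_path / "csp.json"
        model.to_json(path)
        back = CSPModel.from_json(path)
        np.testing.assert_allclose(back.filters, model.filters)
        np.testing.assert_allclose(back.eigenvalues, model.eigenvalues)
        assert back.selected_indices == model.selected_indices
        assert back.band_name == "alpha"
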