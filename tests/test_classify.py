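import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from woundbed.classify import (KernelSpec, SvmModel, _kernel_matrix,
                               bayes_posteriors, fit_bayes, fit_svm,
                               predict_bayes, predict_svm, predict_svm_table,
                               BayesModel)


def make_table(x, labels, prefix="f"):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(labels):
        x = x.T
    df = pd.DataFrame(x, columns=[f"{prefix}{i}" for i in range(x.shape[1])])
    df.insert(0, "image_id", "img")
    df.insert(1, "region_id", [str(i) for i in range(len(labels))])
    df.insert(2, "label", labels)
    return df


class TestBayes:
    def test_identical_marginals_posterior_equals_prior(self):
        table = make_table([0.0, 1.0, 0.0, 1.0],
                           ["granulation", "granulation", "slough", "slough"])
        model = fit_bayes(table)
        label, post = predict_bayes(model, [0.3])
        assert post == pytest.approx([0.5, 0.5], abs=1e-9)
        assert label == "granulation"  # tie broken by class order

    def test_gaussian_likelihood_ratio_closed_form(self):
        # class A fitted as N(0,1), class B as N(2,1), equal priors
        table = make_table([-1, -1, 1, 1, 1, 1, 3, 3],
                           ["granulation"] * 4 + ["slough"] * 4)
        model = fit_bayes(table)
        _, post_mid = predict_bayes(model, [1.0])
        assert post_mid == pytest.approx([0.5, 0.5], abs=1e-9)
        _, post0 = predict_bayes(model, [0.0])
        assert post0[0] == pytest.approx(1.0 / (1.0 + np.exp(-2.0)), abs=1e-9)

    def test_posteriors_normalize(self, rng):
        table = make_table(rng.normal(size=(30, 4)),
                           ["granulation"] * 10 + ["slough"] * 10 + ["necrotic"] * 10)
        model = fit_bayes(table)
        post = bayes_posteriors(model, rng.normal(size=(50, 4)))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_agrees_with_density_product_oracle(self, rng):
        """Posteriors match a direct prior x product-of-normal-pdf evaluation."""
        table = make_table(rng.normal(size=(24, 3)),
                           ["granulation"] * 8 + ["slough"] * 8 + ["necrotic"] * 8)
        model = fit_bayes(table)
        queries = rng.normal(size=(100, 3))
        post = bayes_posteriors(model, queries)
        z = model.standardizer.transform(queries)
        for qi in range(queries.shape[0]):
            joint = np.array([
                model.priors[k]
                * np.prod(stats.norm.pdf(z[qi], model.means[k],
                                         np.sqrt(model.variances[k])))
                for k in range(len(model.classes))
            ])
            np.testing.assert_allclose(post[qi], joint / joint.sum(), rtol=1e-8)

    def test_cross_check_sklearn_gnb(self, rng):
        from sklearn.naive_bayes import GaussianNB
        x = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(3, 1, (20, 2))])
        labels = ["granulation"] * 20 + ["slough"] * 20
        model = fit_bayes(make_table(x, labels))
        z = model.standardizer.transform(x)
        ref = GaussianNB(var_smoothing=1e-12).fit(z, labels)
        queries = rng.normal(1.5, 2, size=(40, 2))
        zq = model.standardizer.transform(queries)
        ours = [predict_bayes(model, q)[0] for q in queries]
        assert (np.asarray(ours) == ref.predict(zq)).mean() >= 0.95

    def test_query_at_class_mean_wins(self, rng):
        x = np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(5, 0.5, (10, 2))])
        model = fit_bayes(make_table(x, ["granulation"] * 10 + ["necrotic"] * 10))
        assert predict_bayes(model, x[:10].mean(axis=0))[0] == "granulation"
        assert predict_bayes(model, x[10:].mean(axis=0))[0] == "necrotic"

    def test_nonfinite_query_rejected(self):
        table = make_table([0.0, 1.0, 2.0, 3.0],
                           ["granulation", "granulation", "slough", "slough"])
        model = fit_bayes(table)
        with pytest.raises(ValueError, match="finite"):
            predict_bayes(model, [np.nan])

    def test_json_roundtrip(self, rng, tmp_path):
        table = make_table(rng.normal(size=(12, 3)),
                           ["granulation"] * 6 + ["slough"] * 6)
        model = fit_bayes(table)
        model.to_json(tmp_path / "m.json")
        back = BayesModel.from_json(tmp_path / "m.json")
        q = rng.normal(size=(5, 3))
        np.testing.assert_allclose(bayes_posteriors(model, q),
                                   bayes_posteriors(back, q), rtol=1e-12)


SEPARABLE = make_table([[0, 0], [0, 1], [4, 0], [4, 1]],
                       ["granulation"] * 2 + ["slough"] * 2)


class TestSvm:
    def test_linear_separable_toy(self):
        model = fit_svm(SEPARABLE, kernel=KernelSpec("linear", C=100.0))
        preds = predict_svm_table(model, SEPARABLE)
        assert (preds == SEPARABLE["label"].to_numpy()).all()
        # the boundary crosses x in (0, 4)
        assert predict_svm(model, [[0.5, 0.5]])[0] == "granulation"
        assert predict_svm(model, [[3.5, 0.5]])[0] == "slough"

    def test_xor_needs_nonlinear_kernel(self):
        xor = make_table([[0, 0], [1, 1], [0, 1], [1, 0]],
                         ["granulation"] * 2 + ["slough"] * 2)
        lin = fit_svm(xor, kernel=KernelSpec("linear", C=100.0))
        acc_lin = (predict_svm_table(lin, xor) == xor["label"].to_numpy()).mean()
        assert acc_lin <= 0.75
        quad = fit_svm(xor, kernel=KernelSpec("poly2", C=100.0))
        assert (predict_svm_table(quad, xor) == xor["label"].to_numpy()).all()

    def test_rbf_kernel_unit_diagonal(self, rng):
        x = rng.normal(size=(7, 3))
        k = _kernel_matrix(KernelSpec("rbf"), gamma=0.7, a=x, b=x)
        assert np.allclose(np.diag(k), 1.0)

    @pytest.mark.parametrize("kernel", ["linear", "poly2", "poly3", "rbf"])
    def test_all_kernels_separate_toy(self, kernel):
        model = fit_svm(SEPARABLE, kernel=KernelSpec(kernel, C=100.0))
        assert (predict_svm_table(model, SEPARABLE) == SEPARABLE["label"].to_numpy()).all()

    def test_serialized_model_predicts_identically(self, rng, tmp_path):
        x = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(2, 1, (15, 3)),
                       rng.normal(-2, 1, (15, 3))])
        labels = ["granulation"] * 15 + ["slough"] * 15 + ["necrotic"] * 15
        model = fit_svm(make_table(x, labels), kernel=KernelSpec("rbf"))
        model.to_json(tmp_path / "svm.json")
        back = SvmModel.from_json(tmp_path / "svm.json")
        q = rng.normal(0, 2, size=(40, 3))
        assert (predict_svm(model, q) == predict_svm(back, q)).all()

    def test_agrees_with_reference_qp(self, rng):
        """Binary linear SVM matches an SLSQP solve of the soft-margin dual."""
        x = np.vstack([rng.normal(-1.0, 0.8, (10, 2)), rng.normal(1.0, 0.8, (10, 2))])
        labels = ["granulation"] * 10 + ["slough"] * 10
        c = 1.0
        model = fit_svm(make_table(x, labels), kernel=KernelSpec("linear", C=c))

        z = model.standardizer.transform(x)
        y = np.where(np.asarray(labels) == "granulation", 1.0, -1.0)
        q = (y[:, None] * y[None, :]) * (z @ z.T)

        def neg_dual(alpha):
            return 0.5 * alpha @ q @ alpha - alpha.sum()

        res = optimize.minimize(
            neg_dual, np.zeros(20), jac=lambda a: q @ a - 1.0,
            bounds=[(0.0, c)] * 20,
            constraints=[{"type": "eq", "fun": lambda a: a @ y}],
            method="SLSQP", options={"maxiter": 500, "ftol": 1e-12},
        )
        assert res.success
        alpha = res.x
        w = (alpha * y) @ z
        margin = (alpha > 1e-6) & (alpha < c - 1e-6)
        b = np.mean(y[margin] - z[margin] @ w)
        ref = np.where(z @ w + b > 0, "granulation", "slough")
        assert (predict_svm(model, x) == ref).all()

    def test_single_class_rejected(self):
        table = make_table([[0, 0], [1, 1]], ["slough", "slough"])
        with pytest.raises(ValueError, match="2 classes"):
            fit_svm(table)


def test_all_five_classifiers_on_separated_clusters(rng):
    """3-class Gaussian clusters >= 4 sigma apart: >= 95% held-out accuracy."""
    centers = np.array([[0, 0], [5, 0], [0, 5]], dtype=float)
    xs, labs = [], []
    from woundbed.features import LABELS
    for c, lab in zip(centers, LABELS):
        xs.append(rng.normal(c, 1.0, size=(60, 2)))
        labs += [lab] * 60
    x = np.vstack(xs)
    labs = np.asarray(labs)
    idx = rng.permutation(len(labs))
    tr, te = idx[:120], idx[120:]
    train = make_table(x[tr], list(labs[tr]))
    test_x = x[te]

    model_b = fit_bayes(train)
    acc = np.mean([predict_bayes(model_b, q)[0] for q in test_x] == labs[te])
    assert acc >= 0.95
    for kernel in ("linear", "poly2", "poly3", "rbf"):
        m = fit_svm(train, kernel=KernelSpec(kernel, C=1.0))
        assert (predict_svm(m, test_x) == labs[te]).mean() >= 0.95
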