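"""The AD definitions: leverage, 1-NN, SVM, 2CC, BB, FC, RTC, variances, baselines."""

import numpy as np
import pytest

from reaction_ad.ad_methods import (
    ADInapplicableWarning,
    ADInputs,
    BoundingBox,
    CompositeAD,
    FragmentControl,
    GaussianProcessAD,
    Leverage,
    OneClassSVMAD,
    OptimisticZero,
    PerfectAD,
    PessimisticZero,
    RandomForestVarianceAD,
    ReactionTypeControl,
    TwoClassClassifierAD,
    ZOneNN,
    twoclass_label,
)
from reaction_ad.reaction_graph import build_cgr, parse_reaction

from conftest import SN2, SN2_ETHYL, ZWITTERION


def _cgrs(*smiles):
    return [build_cgr(parse_reaction(s)) for s in smiles]


# ---------------------------------------------------------------------------
# Leverage


def test_leverage_two_point_hand_example():
    X = np.array([[1.0], [-1.0]])
    lev = Leverage(h_star=0.5).fit(ADInputs(X=X))
    h = lev.score(ADInputs(X=X))
    assert h == pytest.approx([0.5, 0.5])
    assert h.sum() == pytest.approx(1.0)  # = rank(X)


def test_leverage_default_threshold_formula():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 3))
    lev = Leverage().fit(ADInputs(X=X))
    assert lev.threshold == pytest.approx(3 * (3 + 1) / 40)


def test_leverage_centroid_always_inlier():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 4))
    X = X - X.mean(axis=0)
    lev = Leverage().fit(ADInputs(X=X))
    centroid = np.zeros((1, 4))
    assert lev.score(ADInputs(X=centroid))[0] == pytest.approx(0.0)
    assert lev.decide(ADInputs(X=centroid))[0]


@pytest.mark.parametrize("seed", range(5))
def test_leverage_trace_equals_rank(seed):
    """Sum of training leverages equals rank(X) - the hat-matrix trace."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 50))
    m = int(rng.integers(1, 20))
    X = rng.normal(size=(n, m))
    if seed % 2 == 0 and m > 1:  # force rank deficiency
        X[:, -1] = X[:, 0] * 2.0
    lev = Leverage(h_star=1.0).fit(ADInputs(X=X))
    h = lev.score(ADInputs(X=X))
    assert h.sum() == pytest.approx(np.linalg.matrix_rank(X), abs=1e-8)


def test_leverage_boundary_inclusive():
    X = np.array([[1.0], [-1.0]])
    lev = Leverage(h_star=0.5).fit(ADInputs(X=X))
    assert list(lev.decide(ADInputs(X=X))) == [True, True]


# ---------------------------------------------------------------------------
# Z-1NN


def test_z1nn_hand_computation():
    X = np.array([[0.0], [1.0], [2.0]])
    knn = ZOneNN(z=0.5).fit(ADInputs(X=X))
    # NN distances are (1, 1, 1): mean 1, sd 0, Dc = 1 for any Z
    assert knn.mean_ == pytest.approx(1.0)
    assert knn.sd_ == pytest.approx(0.0)
    assert knn.threshold == pytest.approx(1.0)
    assert knn.decide(ADInputs(X=[[1.5]]))[0]       # d = 0.5 <= 1
    assert not knn.decide(ADInputs(X=[[4.5]]))[0]   # d = 2.5 > 1


def test_z1nn_large_z_accepts_everything():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(15, 3))
    test = rng.normal(size=(10, 3)) * 5
    knn = ZOneNN(z=1e9).fit(ADInputs(X=X))
    assert knn.decide(ADInputs(X=test)).all()


def test_z1nn_coverage_monotone_in_threshold():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 2))
    test = rng.normal(size=(40, 2)) * 2
    coverages = []
    for dc in (0.1, 0.5, 1.0, 3.0):
        knn = ZOneNN(dc=dc).fit(ADInputs(X=X))
        coverages.append(knn.decide(ADInputs(X=test)).mean())
    assert coverages == sorted(coverages)


# ---------------------------------------------------------------------------
# one-class SVM


def test_svm_nu_bounds_training_outlier_fraction():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(200, 2))
    for nu in (0.05, 0.2, 0.5):
        svm = OneClassSVMAD(nu=nu, gamma=0.5).fit(ADInputs(X=X))
        outlier_fraction = 1.0 - svm.decide(ADInputs(X=X)).mean()
        assert outlier_fraction <= nu + 0.05  # asymptotic bound, small-n slack


def test_svm_dense_cluster_member_inlier_far_point_outlier():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(100, 2))
    svm = OneClassSVMAD(nu=0.1, gamma=0.5).fit(ADInputs(X=X))
    assert svm.decide(ADInputs(X=X[:1]))[0]
    assert not svm.decide(ADInputs(X=np.full((1, 2), 10.0)))[0]


def test_svm_parameter_validation():
    with pytest.raises(ValueError):
        OneClassSVMAD(nu=0.0)
    with pytest.raises(ValueError):
        OneClassSVMAD(gamma=-1.0)


# ---------------------------------------------------------------------------
# two-class classifier


def test_twoclass_labeling_rule():
    assert list(twoclass_label(np.array([0.1, 3.5]), 1.0)) == [False, True]
    assert list(twoclass_label(np.array([3.0]), 1.0)) == [False]  # boundary inlier
    assert not twoclass_label(np.array([0.5, 1.0]), 1.0).any()


def test_twoclass_degenerate_falls_back_all_inlier():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(20, 3))
    errors = np.abs(rng.normal(0, 0.1, 20))  # no Y-outliers
    with pytest.warns(ADInapplicableWarning):
        clf = TwoClassClassifierAD(n_trees=20).fit(
            ADInputs(X=X, cv_abs_errors=errors, cv_rmse=float(np.sqrt((errors**2).mean())))
        )
    assert clf.degenerate_
    assert clf.decide(ADInputs(X=X)).all()


def test_twoclass_threshold_extremes_and_separable_fixture():
    rng = np.random.default_rng(7)
    # 2 planted gross errors in 30: a larger fraction would inflate the RMSE
    # itself past the point where 3x RMSE can flag them
    X = np.vstack([rng.normal(0, 0.3, (28, 2)), rng.normal(5, 0.3, (2, 2))])
    errors = np.concatenate([np.abs(rng.normal(0, 0.2, 28)), np.full(2, 10.0)])
    ref = float(np.sqrt((errors**2).mean()))
    clf = TwoClassClassifierAD(p_star=0.5, n_trees=60, random_state=0).fit(
        ADInputs(X=X, cv_abs_errors=errors, cv_rmse=ref)
    )
    decisions = clf.decide(ADInputs(X=X))
    assert list(decisions) == list(~twoclass_label(errors, ref))
    clf.p_star = 0.0
    assert clf.decide(ADInputs(X=X)).all()  # probabilities are > 0 here
    clf.p_star = 1.0
    assert not clf.decide(ADInputs(X=X)).any()


# ---------------------------------------------------------------------------
# bounding box / fragment control / reaction type control


def test_bounding_box_training_rows_and_boundaries():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(20, 3))
    bb = BoundingBox().fit(ADInputs(X=X))
    assert bb.decide(ADInputs(X=X)).all()  # self-coverage
    at_max = X.max(axis=0, keepdims=True)
    assert bb.decide(ADInputs(X=at_max))[0]  # closed interval
    beyond = at_max.copy()
    beyond[0, 0] += 1e-6
    assert not bb.decide(ADInputs(X=beyond))[0]


def test_fragment_control_decisions():
    fc = FragmentControl().fit(ADInputs(X=np.zeros((1, 1))))
    dec = fc.decide(ADInputs(unseen_fragments=[frozenset(), frozenset({"X[->>-]Y"})]))
    assert list(dec) == [True, False]


def test_rtc_self_coverage_and_nonnative_rejection():
    train = _cgrs(SN2, SN2_ETHYL)
    rtc = ReactionTypeControl(radius=1).fit(ADInputs(cgrs=train))
    assert rtc.decide(ADInputs(cgrs=train)).all()
    foreign = _cgrs(ZWITTERION)
    assert not rtc.decide(ADInputs(cgrs=foreign))[0]


def test_rtc_change_free_reaction_is_outlier():
    rtc = ReactionTypeControl(radius=1).fit(ADInputs(cgrs=_cgrs(SN2)))
    identity = _cgrs("[CH4:1]>>[CH4:1]")
    assert not rtc.decide(ADInputs(cgrs=identity))[0]


def test_rtc_novel_first_shell_substituent():
    """Native center, novel first-shell group: R=1 rejects, R=0 accepts."""
    amino = "[NH2:4][CH2:1][Br:2].[OH-:3]>>[NH2:4][CH2:1][OH:3].[Br-:2]"
    train = _cgrs(SN2_ETHYL)
    test = _cgrs(amino)
    assert ReactionTypeControl(radius=0).fit(ADInputs(cgrs=train)).decide(
        ADInputs(cgrs=test)
    )[0]
    assert not ReactionTypeControl(radius=1).fit(ADInputs(cgrs=train)).decide(
        ADInputs(cgrs=test)
    )[0]


# ---------------------------------------------------------------------------
# ensemble variance and GPR


def test_rfr_var_thresholds():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(40, 3))
    y = X[:, 0] * 2.0  # exactly learnable
    model = RandomForestVarianceAD(sigma_star=np.inf, n_trees=30, random_state=0).fit(
        ADInputs(X=X, y=y)
    )
    assert model.decide(ADInputs(X=X)).all()  # infinite threshold = OZ
    variance = model.score(ADInputs(X=X))
    assert np.all(variance >= 0)
    model.threshold = -1.0
    zero_var = variance == 0.0
    assert list(model.decide(ADInputs(X=X))) == list(variance <= -1.0)
    # variance 0 is an inlier for any non-negative threshold
    model.threshold = 0.0
    assert np.all(model.decide(ADInputs(X=X))[zero_var])


def test_variance_coverage_monotone_in_threshold():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(50, 3))
    y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.1, 50)
    model = RandomForestVarianceAD(n_trees=40, random_state=1).fit(ADInputs(X=X, y=y))
    test = rng.normal(size=(30, 3)) * 2
    scores = model.score(ADInputs(X=test))
    coverages = [(scores <= t).mean() for t in np.quantile(scores, [0.1, 0.5, 0.9])]
    assert coverages == sorted(coverages)


def test_gpr_variance_smaller_at_training_points():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(30, 2))
    y = X[:, 0] + rng.normal(0, 0.05, 30)
    gpr = GaussianProcessAD(alpha=0.01, gamma=0.5).fit(ADInputs(X=X, y=y))
    var_train = gpr.score(ADInputs(X=X[:5]))
    var_far = gpr.score(ADInputs(X=np.full((5, 2), 8.0)))
    assert np.all(var_train <= var_far)


def test_gpr_predictions_rescaled_to_property_range():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(40, 2))
    y = 100.0 + 10.0 * X[:, 0]
    gpr = GaussianProcessAD(alpha=1e-4, gamma=0.5).fit(ADInputs(X=X, y=y))
    pred = gpr.predict(X)
    assert np.corrcoef(pred, y)[0, 1] > 0.99
    assert abs(pred.mean() - y.mean()) < 5.0


# ---------------------------------------------------------------------------
# baselines and composites


def test_zero_models():
    inputs = ADInputs(X=np.zeros((7, 1)))
    assert OptimisticZero().fit(inputs).decide(inputs).all()
    assert not PessimisticZero().fit(inputs).decide(inputs).any()


def test_perfect_model_definition():
    errors = np.array([0.1, 2.9, 3.1])
    inputs = ADInputs(cv_abs_errors=errors, cv_rmse=1.0)
    perfect = PerfectAD().fit(inputs)
    assert list(perfect.decide(inputs)) == [True, True, False]
    clean = ADInputs(cv_abs_errors=np.array([0.0, 0.1]), cv_rmse=1.0)
    assert perfect.decide(clean).all()


def test_composite_identities():
    inputs = ADInputs(X=np.random.default_rng(13).normal(size=(10, 2)))
    oz, pz = OptimisticZero(), PessimisticZero()
    bb = BoundingBox()
    for single in (oz, bb):
        single.fit(inputs)
    composite_oz = CompositeAD([OptimisticZero(), BoundingBox()]).fit(inputs)
    assert list(composite_oz.decide(inputs)) == list(bb.decide(inputs))
    composite_pz = CompositeAD([PessimisticZero(), BoundingBox()]).fit(inputs)
    assert not composite_pz.decide(inputs).any()
    single = CompositeAD([BoundingBox()]).fit(inputs)
    assert list(single.decide(inputs)) == list(bb.decide(inputs))


def test_composite_truth_table():
    class Fixed(OptimisticZero):
        def __init__(self, value):
            self.value = value

        def decide(self, inputs):
            return np.full(len(inputs), self.value)

    inputs = ADInputs(X=np.zeros((1, 1)))
    assert CompositeAD([Fixed(True), Fixed(True)]).fit(inputs).decide(inputs)[0]
    assert not CompositeAD([Fixed(True), Fixed(False)]).fit(inputs).decide(inputs)[0]
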