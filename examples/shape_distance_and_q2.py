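"""Closed-form L2 distance between grain-weight distributions.

Compares an observed mixture with a slightly mis-predicted one, showing
the squared L2 distance between the two densities computed in closed
form (no numerical integration), and then scores a three-cultivar
"population" with PRESS and the shape-level skill score Q^2: 1 means
the predicted densities coincide with the observed ones, 0 means no
better than predicting the population-mean parameters for everyone.
"""

import grainfill as gf
from grainfill.shape import PredictionSet

observed = [
    gf.MixtureParams.from_values(0.12, 1.6, 3.5, 110.0, 0.23),
    gf.MixtureParams.from_values(0.20, 1.4, 4.5, 95.0, 0.26),
    gf.MixtureParams.from_values(0.33, 2.0, 3.0, 80.0, 0.28),
]
# a "prediction" that shrinks every cultivar toward the middle one
predicted = [
    gf.MixtureParams.from_values(0.16, 1.5, 4.0, 102.0, 0.245),
    gf.MixtureParams.from_values(0.20, 1.4, 4.5, 95.0, 0.26),
    gf.MixtureParams.from_values(0.27, 1.7, 3.7, 88.0, 0.27),
]

d = gf.squared_l2_distance(observed[0], predicted[0])
print(f"squared L2 distance, cultivar 1 observed vs predicted: {d:.5f} (1/mg)")

pset = PredictionSet(("c1", "c2", "c3"), tuple(observed), tuple(predicted))
print(f"PRESS over 3 cultivars: {gf.press(pset):.5f}")
print(f"shape Q^2: {gf.q2_shape(pset):.3f} "
      "(> 0: better than the mean-parameter predictor)")

perfect = PredictionSet(("c1", "c2", "c3"), tuple(observed), tuple(observed))
print(f"shape Q^2 with perfect predictions: {gf.q2_shape(perfect):.3f}")
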