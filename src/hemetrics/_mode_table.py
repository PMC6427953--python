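"""Frozen idealized minimal-basis mode table.

Six orthonormal out-of-plane z-weight vectors in canonical atom order
(rows: sad, ruf, dom, wav_x, wav_y, pro), orthogonal to the rigid-body
null space and stored at full float64 precision so the orthonormality
invariant holds to 1e-10.  Generated once from the symmetry-adapted
construction in hemetrics.nsd and frozen here as the "static-table"
provenance source, guarding the constructive code path against drift.
"""

STATIC_MODE_TABLE = [
    [-2.5028273616662106e-18,
     0.1496744410942252,
     0.32030854138335324,
     0.32030854138335324,
     0.1496744410942252,
     5.017915600701367e-18,
     4.404663100427264e-18,
     -0.14967444109422517,
     -0.32030854138335324,
     -0.32030854138335324,
     -0.1496744410942252,
     6.451434018218127e-18,
     -1.31868613959304e-18,
     0.14967444109422515,
     0.32030854138335313,
     0.32030854138335324,
     0.1496744410942252,
     -8.839429101960618e-18,
     -8.226176601686513e-18,
     -0.14967444109422512,
     -0.32030854138335313,
     -0.32030854138335324,
     -0.14967444109422523,
     -1.0272947519477376e-17],
    [2.6594655978099202e-17,
     0.2321013977673292,
     0.1079571085986664,
     -0.10795710859866643,
     -0.23210139776732924,
     -0.3448889788249771,
     -5.560302778521499e-17,
     -0.23210139776732924,
     -0.10795710859866642,
     0.10795710859866636,
     0.2321013977673292,
     0.34488897882497704,
     8.523474142661563e-17,
     0.23210139776732924,
     0.10795710859866656,
     -0.10795710859866652,
     -0.23210139776732922,
     -0.34488897882497704,
     -8.598788519759466e-17,
     -0.23210139776732924,
     -0.10795710859866652,
     0.10795710859866656,
     0.23210139776732922,
     0.3448889788249771],
    [0.397705615313889,
     0.033703865704566745,
     -0.20896396736831477,
     -0.20896396736831477,
     0.033703865704566745,
     -0.047185411986393776,
     0.397705615313889,
     0.03370386570456675,
     -0.20896396736831477,
     -0.20896396736831477,
     0.03370386570456678,
     -0.04718541198639374,
     0.397705615313889,
     0.03370386570456678,
     -0.20896396736831477,
     -0.20896396736831477,
     0.03370386570456675,
     -0.047185411986393776,
     0.397705615313889,
     0.033703865704566745,
     -0.20896396736831477,
     -0.20896396736831477,
     0.033703865704566745,
     -0.04718541198639379],
    [0.5456943935356403,
     0.1618849897087925,
     -0.2620438443158887,
     -0.2620438443158887,
     0.1618849897087921,
     0.023313226519317796,
     3.7373511552620035e-17,
     0.06262376373278809,
     -0.04206953624914597,
     0.04206953624914581,
     -0.06262376373278819,
     -0.02331322651931821,
     -0.5456943935356405,
     -0.1618849897087925,
     0.2620438443158886,
     0.2620438443158886,
     -0.16188498970879237,
     -0.02331322651931833,
     -1.1638989295427955e-16,
     -0.06262376373278819,
     0.04206953624914588,
     -0.04206953624914604,
     0.06262376373278802,
     0.023313226519317727],
    [7.655508054567605e-17,
     -0.062623763732788,
     0.04206953624914598,
     -0.04206953624914587,
     0.06262376373278798,
     0.023313226519317918,
     0.5456943935356405,
     0.16188498970879212,
     -0.2620438443158887,
     -0.26204384431588884,
     0.16188498970879198,
     0.023313226519317918,
     1.0519774980154277e-16,
     0.06262376373278809,
     -0.04206953624914605,
     0.04206953624914591,
     -0.06262376373278797,
     -0.0233132265193179,
     -0.5456943935356405,
     -0.16188498970879225,
     0.26204384431588895,
     0.2620438443158887,
     -0.16188498970879198,
     -0.023313226519317918],
    [-6.517780427499874e-17,
     0.30316953129541624,
     0.18190171877724978,
     -0.1819017187772497,
     -0.30316953129541624,
     1.3639118020848818e-17,
     -1.8624470732321852e-17,
     0.30316953129541624,
     0.18190171877724975,
     -0.18190171877724975,
     -0.30316953129541624,
     -1.798906918925566e-17,
     6.686520839913067e-17,
     0.30316953129541624,
     0.1819017187772497,
     -0.18190171877724978,
     -0.30316953129541624,
     6.025877801461748e-18,
     2.0311874856453766e-17,
     0.30316953129541624,
     0.18190171877724975,
     -0.18190171877724975,
     -0.30316953129541624,
     -2.0763276116623335e-18],
]
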