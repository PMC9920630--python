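"""Windowed emotion recognition over a streaming trace.

Trains the four binary quadrant models on a small corpus, then classifies
a 3-minute high-arousal stream in tumbling 30 s windows, printing one
(flags, probabilities) record per window — the format the decision layer
of a music-recommender app would consume.
"""

import json

import edaffect as ea

profiles = ea.default_profiles()
segments = []
seed = 100
for quadrant in ea.QUADRANT_ORDER:
    for i in range(10):
        session, _ = ea.generate_segment(profiles[quadrant], duration=60.0, rate=8.0, seed=seed)
        seed += 1
        segments.append(ea.LabeledSegment(label=quadrant, session=session, source_session="train", song_index=i))
table = ea.normalize(ea.build_feature_table(segments))

search = ea.SearchSpace(algorithms=("RF", "KNN"), n_features_grid=(5, 15), n_iter=2)
models = {
    q: ea.train_and_tune(
        table,
        ea.rank_features(table, target=q.value, seed=0),
        architecture=q.value,
        search=search,
        cv=ea.CVConfig(folds=5, repeats=2),
        seed=0,
    )
    for q in ea.QUADRANT_ORDER
}

stream, _ = ea.generate_segment(profiles[ea.QuadrantLabel.HAPPY], duration=180.0, rate=8.0, seed=7)
print("streaming a Happy-profile trace; one record per 30 s window (Happy, Sad, Aggressive, Relaxed):")
for start, pred in ea.run_windowed_recognition(stream, models, table, ea.WindowConfig(30.0, 30.0)):
    record = {"t": start, "flags": list(pred.flags), "probs": [round(p, 2) for p in pred.probabilities]}
    print(json.dumps(record))
print("A flag is true when that quadrant's probability reaches the 0.5 threshold.")
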