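{"type": "Polygon", "coordinates": [[[121.0, 21.0], [121.0, 33.0], [100.0, 33.0], [100.0, 21.0], [121.0, 21.0]]]}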