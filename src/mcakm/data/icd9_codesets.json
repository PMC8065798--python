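{
  "lung_cancer": ["162.XX"],
  "depression": ["296.2X-296.3X", "300.4", "311.X"],
  "anxiety": ["300.XX", "291.89", "292.89"],
  "bipolar": ["296.0", "296.1", "296.4", "296.5", "296.6", "296.7", "296.8", "296.80", "296.89"],
  "alcohol_induced": ["V113", "9800", "2650", "2651", "3575", "4255", "3050", "291", "303", "571.0-571.3"]
}
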