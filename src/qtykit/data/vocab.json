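{
  "_comment": "Closed label vocabularies for annotation tables. Seven functional categories of cancer-related membrane proteins and the seventeen cancer types they are annotated against. User-extensible: pass a custom vocabulary file to the annotation reader.",
  "categories": [
    "receptor",
    "transporter",
    "carrier",
    "channel",
    "enzyme",
    "contact",
    "other"
  ],
  "cancers": [
    "breast cancer",
    "cervical cancer",
    "colorectal cancer",
    "endometrial cancer",
    "glioma",
    "head and neck cancer",
    "liver cancer",
    "lung cancer",
    "melanoma",
    "ovarian cancer",
    "pancreatic cancer",
    "prostate cancer",
    "renal cancer",
    "stomach cancer",
    "testis cancer",
    "thyroid cancer",
    "urothelial cancer"
  ]
}
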