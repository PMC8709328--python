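{
  "cirrhotic|no_washout|centrifugal": "fnh",
  "cirrhotic|no_washout|iso": "regenerative_nodule",
  "cirrhotic|no_washout|peripheral_nodular": "haemangioma",
  "cirrhotic|no_washout|peripheral_septa": "abscess",
  "cirrhotic|washout|hyper": "hcc",
  "cirrhotic|washout|rim": "metastasis",
  "cirrhotic|washout|rim_central_hypo": "cholangiocarcinoma",
  "non_cirrhotic|no_washout|centrifugal": "fnh",
  "non_cirrhotic|no_washout|iso": "focal_fatty_change",
  "non_cirrhotic|no_washout|peripheral_nodular": "haemangioma",
  "non_cirrhotic|no_washout|peripheral_septa": "abscess",
  "non_cirrhotic|washout|hyper": "hcc",
  "non_cirrhotic|washout|rim": "metastasis",
  "non_cirrhotic|washout|rim_central_hypo": "cholangiocarcinoma"
}
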