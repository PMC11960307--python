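# Synthetic PT -> SOC dictionary (stand-in for the licensed MedDRA terminology).
# Format: pt$soc_name$soc_code — one row per Preferred Term, primary SOC only.
# Covers all 26 System Organ Classes with representative calcimimetic-domain PTs.
Shunt stenosis$Injury, poisoning and procedural complications$10022117
Shunt aneurysm$Injury, poisoning and procedural complications$10022117
Shunt occlusion$Injury, poisoning and procedural complications$10022117
Shunt malfunction$Injury, poisoning and procedural complications$10022117
Arteriovenous fistula site haemorrhage$Injury, poisoning and procedural complications$10022117
Heat illness$Injury, poisoning and procedural complications$10022117
Nausea$Gastrointestinal disorders$10017947
Vomiting$Gastrointestinal disorders$10017947
Diarrhoea$Gastrointestinal disorders$10017947
Drug ineffective$General disorders and administration site conditions$10018065
Fatigue$General disorders and administration site conditions$10018065
Blood parathyroid hormone increased$Investigations$10022891
Blood parathyroid hormone decreased$Investigations$10022891
Blood parathyroid hormone abnormal$Investigations$10022891
Blood calcium decreased$Investigations$10022891
Blood calcium abnormal$Investigations$10022891
Blood phosphorus increased$Investigations$10022891
Blood phosphorus abnormal$Investigations$10022891
Adjusted calcium decreased$Investigations$10022891
Electrocardiogram QT prolonged$Investigations$10022891
Shunt infection$Infections and infestations$10021881
Puncture site infection$Infections and infestations$10021881
Hepatic cyst infection$Infections and infestations$10021881
Renal cyst infection$Infections and infestations$10021881
Diabetic gangrene$Infections and infestations$10021881
Pyoderma$Infections and infestations$10021881
Putamen haemorrhage$Nervous system disorders$10029205
Thalamus haemorrhage$Nervous system disorders$10029205
Headache$Nervous system disorders$10029205
Aortic valve stenosis$Cardiac disorders$10007541
Cardiac failure$Cardiac disorders$10007541
Hungry bone syndrome$Musculoskeletal and connective tissue disorders$10028395
Muscle spasms$Musculoskeletal and connective tissue disorders$10028395
Hypocalcaemia$Metabolism and nutrition disorders$10027433
Hypophosphataemia$Metabolism and nutrition disorders$10027433
Calciphylaxis$Metabolism and nutrition disorders$10027433
Pruritus$Skin and subcutaneous tissue disorders$10040785
Dialysis hypotension$Vascular disorders$10047065
Peripheral arterial occlusive disease$Vascular disorders$10047065
Hypotension$Vascular disorders$10047065
Dyspnoea$Respiratory, thoracic and mediastinal disorders$10038738
Parathyroid tumour benign$Neoplasms benign, malignant and unspecified (incl cysts and polyps)$10029104
Insomnia$Psychiatric disorders$10037175
Hepatic function abnormal$Hepatobiliary disorders$10019805
Parathyroidectomy$Surgical and medical procedures$10042613
Vision blurred$Eye disorders$10015919
Anaemia$Blood and lymphatic system disorders$10005329
Device occlusion$Product issues$10077536
Hypersensitivity$Immune system disorders$10021428
Renal impairment$Renal and urinary disorders$10038359
Hyperparathyroidism secondary$Endocrine disorders$10014698
Tinnitus$Ear and labyrinth disorders$10013993
Gynaecomastia$Reproductive system and breast disorders$10038604
Treatment noncompliance$Social circumstances$10041244
Polycystic kidney disease$Congenital, familial and genetic disorders$10010331
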