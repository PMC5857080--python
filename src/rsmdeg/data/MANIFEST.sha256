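994b54fa9f530fb0b33af519407bccc936c39349af7200a7a0390dd7c1b7dbee  eq_adl15.json
334ae54599f51f510a689c4c86f1026866d78d076281c37b903a742b035ec43b  eq_adl36.json
6063a7bc05935f56d6224d8061a67ef5972bc894c2bcfb0164ef8366cda3548e  table1_factors.csv
f1f175313b720b7d5cade9eef8b0cb5df3632eaa4c9cc4078a906a246fc5d4eb  table2_adl15.csv
799efefa95b308bc592432f439a70b6b328132858a16f7d0b0346a7aa82c0792  table4_adl36.csv
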