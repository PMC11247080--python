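district,dominant_crop,predicted_crops
"Udaipur, Rajasthan",Wheat,Wheat
"Raipur, Chattisgarh",Wheat,Rice
"Palampur, HP",Wheat,Wheat
"Anand, Gujarat",Wheat,Wheat
"Jabalpur, MP",Soybean,Rice
"Faizabad, UP",Chickpea,Chickpea
"Parbhani, Maharashtra",Cotton,Cotton
"Anantapur, AP",Groundnut,Groundnut
"Bangalore, Karnataka",Groundnut,Groundnut
"Jammu, J&K",Maize,Rice
"Hisar, Haryana",Mustard,Mustard
"Ranchi, Jharkhand",Rice,Rice
"Ludhiana, Punjab",Wheat,Wheat
"Thrissur, Kerala",Rice,Rice
"Jorhat, Assam",Rice,Rice
"Kanpur, UP",Rice,Wheat
"Dapoli, Maharashtra",Rice,Rice
"Bhubaneswar, Orissa",Rice,Rice
"Mohanpur, UP",Rice,Wheat
"Kovilpatti, TN",Rice,Rice
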